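"""End-to-end orchestration and reporting.

``run_pipeline`` executes the full analysis — read simulation (or ingestion),
peak calling at a stringency gradient, swap-FDR, genomic annotation,
condition comparison, overlap statistics, NRI stratification profiles, and
the expression arm — and emits a deterministic JSON report plus per-stage
TSV/BED files.  ``consistency_checks`` recomputes printed percentages and
totals from their raw counts with explicit rounding.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from relochip import __version__
from relochip.annotation import GeneIndex, annotate_peakset
from relochip.enrichment import directional_overlap, venn3
from relochip.expression import (
    call_hormone_regulated,
    chd8_dependence,
    proximity_enrichment,
    regulation_change_summary,
)
from relochip.genome_core import GenomicInterval
from relochip.peak_calling import PeakCallParams, PeakSet, call_peaks, empirical_fdr, peaks_to_bed
from relochip.profiles import stratify_by_score, tag_density_profile
from relochip.synthetic_data import SimConfig, Simulation

__all__ = ["RunConfig", "run_pipeline", "consistency_checks", "compare_conditions", "round_half_away"]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (1e-10, 1e-15, 1e-20)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full synthetic-study run.

    ``sim`` defines the study conditions (including the root seed from
    which every stage's randomness is derived); ``p_thresholds`` the peak
    stringency gradient; ``main_threshold`` the level used for annotation
    and downstream overlap/expression statistics.  ``percent_decimals``
    controls report rounding (half away from zero).
    """

    sim: SimConfig = field(default_factory=SimConfig)
    p_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    main_threshold: float = 1e-10
    bin_size: int = 200
    promoter_bp: int = 2000
    fc_threshold: float = 1.5
    alpha: float = 0.01
    criterion: str = "fdr"
    dependence_hi: float = 1.20
    dependence_lo: float = 0.8
    percent_decimals: int = 1
    with_expression: bool = True
    out_dir: str | None = None


def round_half_away(x: float, digits: int = 0) -> float:
    """Round half away from zero (the convention of the reported
    percentages), unlike banker's rounding."""
    factor = 10.0**digits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def compare_conditions(
    peaks_a: PeakSet | Sequence[GenomicInterval],
    peaks_b: PeakSet | Sequence[GenomicInterval],
) -> dict:
    """Directional sharing between two peak sets.

    ``shared`` regions of A overlap >= 1 region of B (and vice versa);
    ``specific`` is the complement.  Both directions are reported.
    """
    ivs_a = peaks_a.intervals if isinstance(peaks_a, PeakSet) else list(peaks_a)
    ivs_b = peaks_b.intervals if isinstance(peaks_b, PeakSet) else list(peaks_b)
    if not ivs_a and not ivs_b:
        return {
            "n_A": 0, "n_B": 0, "n_A_shared": 0, "n_B_shared": 0,
            "A_shared": [], "A_specific": [], "B_shared": [], "B_specific": [],
        }
    from relochip.genome_core import IntervalIndex

    idx_a = IntervalIndex(ivs_a)
    idx_b = IntervalIndex(ivs_b)
    a_shared = [iv for iv in ivs_a if idx_b.any_overlap(iv)]
    b_shared = [iv for iv in ivs_b if idx_a.any_overlap(iv)]
    return {
        "n_A": len(ivs_a),
        "n_B": len(ivs_b),
        "n_A_shared": len(a_shared),
        "n_B_shared": len(b_shared),
        "A_shared": a_shared,
        "A_specific": [iv for iv in ivs_a if not idx_b.any_overlap(iv)],
        "B_shared": b_shared,
        "B_specific": [iv for iv in ivs_b if not idx_a.any_overlap(iv)],
    }


def consistency_checks(rows: Sequence[Mapping]) -> pd.DataFrame:
    """Recompute printed percentages/totals from raw counts.

    Each row is either ``{"label", "numerator", "denominator", "digits",
    "printed"}`` (a percentage) or ``{"label", "addends", "printed"}``
    (a total).  Returns a table with the recomputed value and a match flag;
    zero denominators are flagged, not raised.
    """
    out = []
    for row in rows:
        label = row.get("label", "")
        printed = row.get("printed")
        if "addends" in row:
            value: float | None = float(sum(row["addends"]))
        else:
            num, den = row["numerator"], row["denominator"]
            digits = int(row.get("digits", 1))
            value = None if den == 0 else round_half_away(100.0 * num / den, digits)
        ok = None if printed is None or value is None else bool(
            abs(value - float(printed)) < 1e-9
        )
        out.append({"label": label, "computed": value, "printed": printed, "matches": ok})
    return pd.DataFrame(out)


def _peak_params(config: RunConfig, threshold: float) -> PeakCallParams:
    return PeakCallParams(
        bin_size=config.bin_size,
        p_threshold=threshold,
        fragment_length=config.sim.fragment_length,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on the configured synthetic study.

    Returns the summary report as a plain dict (JSON-serializable,
    deterministically ordered).  When ``config.out_dir`` is set, the report
    plus per-stage BED/TSV outputs are written there.
    """
    sim = Simulation(config.sim)
    gene_index = GeneIndex(sim.genes)
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.sim.seed,
            "config": _config_dict(config),
        },
        "conditions": {},
    }
    peaksets: dict[str, PeakSet] = {}
    for condition in ("baseline", "hormone"):
        logger.info("stage=peaks condition=%s", condition)
        chip = sim.simulate_reads(condition, "chip")
        control = sim.simulate_reads(condition, "control")
        per_threshold = {}
        main_set: PeakSet | None = None
        for thr in config.p_thresholds:
            ps = call_peaks(chip, control, sim.chrom_sizes, _peak_params(config, thr))
            per_threshold[f"{thr:g}"] = ps.n_peaks
            if thr == config.main_threshold:
                main_set = ps
        if main_set is None:
            main_set = call_peaks(
                chip, control, sim.chrom_sizes, _peak_params(config, config.main_threshold)
            )
        fdr, n_real, n_pseudo = empirical_fdr(
            chip, control, sim.chrom_sizes, _peak_params(config, config.main_threshold)
        )
        records, table = annotate_peakset(main_set, gene_index, config.promoter_bp)
        peaksets[condition] = main_set
        report["conditions"][condition] = {
            "n_peaks_by_threshold": per_threshold,
            "fdr": fdr,
            "n_real": n_real,
            "n_pseudo": n_pseudo,
            "category_counts": {k: int(v) for k, v in table.items()},
            "category_pct": {
                k: round_half_away(100.0 * v / max(table.sum(), 1), config.percent_decimals)
                for k, v in table.items()
            },
        }
        report["conditions"][condition]["_records"] = records  # stripped before JSON

    logger.info("stage=compare_conditions")
    comp = compare_conditions(peaksets["baseline"], peaksets["hormone"])
    report["condition_comparison"] = {
        k: comp[k] for k in ("n_A", "n_B", "n_A_shared", "n_B_shared")
    }

    logger.info("stage=overlaps")
    prbs_iv = [s.interval for s in sim.prbs]
    hp = peaksets["hormone"].intervals
    if hp:
        ov = directional_overlap(hp, prbs_iv)
        report["hormone_peaks_vs_prbs"] = {
            "n_peaks": ov.nA,
            "n_prbs": ov.nB,
            "n_peaks_hit": ov.nA_hit,
            "pct_peaks_at_prbs": round_half_away(ov.pct_A, config.percent_decimals),
            "pct_prbs_hit": round_half_away(ov.pct_B, config.percent_decimals),
        }

    logger.info("stage=nri_strata")
    top, bottom = stratify_by_score(sim.prbs, 0.10, 0.10)
    chip_h = sim.simulate_reads("hormone", "chip")
    prof_top = tag_density_profile(
        chip_h, top, sim.chrom_sizes, fragment_length=config.sim.fragment_length
    )
    prof_bot = tag_density_profile(
        chip_h, bottom, sim.chrom_sizes, fragment_length=config.sim.fragment_length
    )
    report["nri_strata"] = {
        "top_central_density": prof_top.central_bin_density,
        "bottom_central_density": prof_bot.central_bin_density,
    }

    if config.with_expression:
        logger.info("stage=expression")
        matrix, truth = sim.simulate_expression()
        calls = call_hormone_regulated(
            matrix, fc_threshold=config.fc_threshold, alpha=config.alpha,
            criterion=config.criterion,
        )
        calls = chd8_dependence(
            calls, matrix, hi=config.dependence_hi, lo=config.dependence_lo
        )
        n_up = int((calls.regulated == "up").sum())
        n_down = int((calls.regulated == "down").sum())
        dep_ids = set(calls.index[calls.dependent])
        target_ids = set(sim.peak_target_genes.values())
        prox = proximity_enrichment(dep_ids, target_ids, len(sim.genes))
        summary = regulation_change_summary(calls)
        report["expression"] = {
            "criterion": config.criterion,
            "n_regulated": n_up + n_down,
            "n_up": n_up,
            "n_down": n_down,
            "n_dependent": int(calls.dependent.sum()),
            "n_dependent_peak_proximal": prox.k,
            "proximity_log10_p": prox.log10_p,
            "fc_summary": {
                f"{d}|{a}": {k: _jsonable(v) for k, v in row.items()}
                for (d, a), row in summary.iterrows()
            },
        }
        report["expression"]["_calls"] = calls  # stripped before JSON
    else:
        report["expression"] = {"status": "absent (no expression inputs)"}

    report["report_sha256"] = report_hash(report)
    if config.out_dir:
        _write_outputs(Path(config.out_dir), config, sim, peaksets, report)
    return report


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, float) and math.isnan(v):
        return None
    return v


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    # where the report is written is not part of its scientific content,
    # so it does not enter the provenance block or the determinism hash
    d.pop("out_dir", None)
    return d


def _strip_private(obj):
    if isinstance(obj, dict):
        return {k: _strip_private(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_strip_private(v) for v in obj]
    return _jsonable(obj)


def report_json(report: dict) -> str:
    """Canonical JSON text of a report (private stage objects stripped,
    keys sorted) — the text whose hash defines run determinism."""
    clean = _strip_private({k: v for k, v in report.items() if k != "report_sha256"})
    return json.dumps(clean, sort_keys=True, indent=2)


def report_hash(report: dict) -> str:
    return hashlib.sha256(report_json(report).encode()).hexdigest()


def _write_outputs(out: Path, config: RunConfig, sim: Simulation, peaksets, report: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for condition, ps in peaksets.items():
        peaks_to_bed(ps, out / f"peaks_{condition}.bed")
        recs = report["conditions"][condition].get("_records")
        if recs:
            pd.DataFrame([dataclasses.asdict(r) for r in recs]).to_csv(
                out / f"annotation_{condition}.tsv", sep="\t", index=False
            )
    if "_calls" in report.get("expression", {}):
        report["expression"]["_calls"].to_csv(out / "gene_calls.tsv", sep="\t")
    (out / "report.json").write_text(report_json(report) + "\n")
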