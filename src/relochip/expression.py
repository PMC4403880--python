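"""Expression arm: hormone-regulated gene calls, knockdown-dependence
classification by the linear fold-change ratio rule, proximity enrichment,
and qPCR/eRNA fold-induction arithmetic.

The design is a 2 x 2 factorial (treatment: vehicle ``EtOH`` vs progestin
``R5020``; knockdown: control ``siCt`` vs factor-targeting ``siCHD8``) with
replicated log2 intensities.  A gene is hormone-regulated when its linear
fold change in the control arm clears a threshold (default 1.5) with a
significant Welch t-test (default: Benjamini-Hochberg FDR <= 0.01).
Knockdown dependence uses the ratio R = FC_kd / FC_ct of linear hormone
fold changes; dependence is declared for regulated genes with R strictly
above 1.20 or strictly below 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from relochip.enrichment import HypergeomTest, hypergeometric_overlap_pvalue

__all__ = [
    "TREATMENTS",
    "KNOCKDOWNS",
    "ExpressionMatrix",
    "call_hormone_regulated",
    "chd8_dependence",
    "proximity_enrichment",
    "regulation_change_summary",
    "fold_induction",
]

TREATMENTS = ("EtOH", "R5020")
KNOCKDOWNS = ("siCt", "siCHD8")


class ExpressionMatrix:
    """Log2 expression values over a complete 2 x 2 x r design.

    ``values``: genes x samples DataFrame of log2 intensities (no missing
    values).  ``samples``: per-sample metadata with columns ``treatment``
    (EtOH/R5020), ``knockdown`` (siCt/siCHD8) and ``replicate``.
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = set(values.columns) - set(samples.index)
        if missing:
            raise ValueError(f"samples table lacks metadata for {sorted(missing)}")
        cells = samples.groupby(["treatment", "knockdown"], observed=True).size()
        for t in TREATMENTS:
            for k in KNOCKDOWNS:
                r = int(cells.get((t, k), 0))
                if r < 2:
                    raise ValueError(
                        f"design cell ({t}, {k}) has {r} replicates; need >= 2"
                    )
        self.values = values
        self.samples = samples.loc[list(values.columns)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def arm(self, knockdown: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(R5020 columns, EtOH columns) within one knockdown arm."""
        meta = self.samples
        treated = meta.index[(meta.knockdown == knockdown) & (meta.treatment == "R5020")]
        vehicle = meta.index[(meta.knockdown == knockdown) & (meta.treatment == "EtOH")]
        return self.values[list(treated)], self.values[list(vehicle)]

    def to_tsv(self, values_path: str | Path, samples_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, values_path: str | Path, samples_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
        return cls(values, samples)


# strict threshold comparisons with a relative guard so a gene sitting
# exactly on a boundary (FC = 1.5, R = 1.20 or 0.8) is never called on
# floating-point round-off alone
_REL_EPS = 1e-9


def _strictly_above(values: np.ndarray, threshold: float) -> np.ndarray:
    return values > threshold * (1.0 + _REL_EPS)


def _strictly_below(values: np.ndarray, threshold: float) -> np.ndarray:
    return values < threshold * (1.0 - _REL_EPS)


def _arm_fold_change(matrix: ExpressionMatrix, knockdown: str) -> pd.Series:
    treated, vehicle = matrix.arm(knockdown)
    return np.exp2(treated.mean(axis=1) - vehicle.mean(axis=1))


def _welch_pvalues(treated: pd.DataFrame, vehicle: pd.DataFrame) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(treated.values, vehicle.values, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    # zero within-group variance leaves the t statistic undefined: resolve
    # deterministically by comparing the means
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same = np.isclose(treated.values.mean(axis=1), vehicle.values.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return p


def call_hormone_regulated(
    matrix: ExpressionMatrix,
    arm: str = "siCt",
    fc_threshold: float = 1.5,
    alpha: float = 0.01,
    criterion: str = "fdr",
) -> pd.DataFrame:
    """Call hormone-regulated genes within one knockdown arm.

    Per gene: linear fold change ``fc_ct = 2^(mean log2 R5020 - mean log2
    EtOH)``, two-sided Welch t-test on the log2 values, Benjamini-Hochberg
    q-values across all genes.  ``regulated`` is ``up`` when
    ``fc_ct > fc_threshold`` (strict) with the chosen statistic
    (``fdr`` -> q, ``pvalue`` -> p) <= alpha, ``down`` symmetrically for
    ``fc_ct < 1/fc_threshold``, else ``none``.
    """
    if criterion not in ("fdr", "pvalue"):
        raise ValueError(f"criterion must be 'fdr' or 'pvalue', got {criterion!r}")
    treated, vehicle = matrix.arm(arm)
    fc = _arm_fold_change(matrix, arm)
    p = _welch_pvalues(treated, vehicle)
    q = multipletests(p, method="fdr_bh")[1]
    stat = q if criterion == "fdr" else p
    regulated = np.where(
        _strictly_above(fc.values, fc_threshold) & (stat <= alpha),
        "up",
        np.where(
            _strictly_below(fc.values, 1.0 / fc_threshold) & (stat <= alpha),
            "down",
            "none",
        ),
    )
    return pd.DataFrame(
        {
            "fc_ct": fc.values,
            "p_value": p,
            "q_value": q,
            "regulated": regulated,
        },
        index=matrix.gene_ids,
    )


def chd8_dependence(
    calls: pd.DataFrame,
    matrix: ExpressionMatrix,
    hi: float = 1.20,
    lo: float = 0.8,
    kd_arm: str = "siCHD8",
) -> pd.DataFrame:
    """Fill the knockdown-dependence ratio and flag.

    ``R = fc_kd / fc_ct`` on the linear fold-change scale; a gene is
    dependent iff it is hormone-regulated and R is strictly above ``hi`` or
    strictly below ``lo``.
    """
    out = calls.copy()
    out["fc_kd"] = _arm_fold_change(matrix, kd_arm).reindex(out.index).values
    out["dependence_ratio"] = out["fc_kd"] / out["fc_ct"]
    R = out["dependence_ratio"].values
    out["dependent"] = (out["regulated"] != "none") & (
        _strictly_above(R, hi) | _strictly_below(R, lo)
    )
    return out


def proximity_enrichment(
    dependent_genes: Iterable[str],
    peak_target_genes: Iterable[str],
    universe_gene_count: int,
) -> HypergeomTest:
    """Hypergeometric enrichment of dependent genes among peak-proximal
    genes (genes that are the nearest-gene assignment of >= 1 peak)."""
    dep = set(dependent_genes)
    targets = set(peak_target_genes)
    return hypergeometric_overlap_pvalue(
        N=universe_gene_count, K=len(targets), n=len(dep), k=len(dep & targets)
    )


def _box_stats(x: np.ndarray) -> dict[str, float]:
    if len(x) == 0:
        return {k: float("nan") for k in ("median", "q1", "q3", "whisker_lo", "whisker_hi")} | {
            "n": 0
        }
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_candidates = x[x >= q1 - 1.5 * iqr]
    hi_candidates = x[x <= q3 + 1.5 * iqr]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(lo_candidates.min()),
        "whisker_hi": float(hi_candidates.max()),
        "n": int(len(x)),
    }


def regulation_change_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Box-plot summaries (median, quartiles, 1.5 x IQR whiskers) of the
    linear hormone fold change, per regulation direction and knockdown arm.

    ``calls`` must carry ``regulated``, ``fc_ct`` and ``fc_kd`` columns
    (i.e. the output of :func:`chd8_dependence`).  Rows are indexed by
    (direction, arm); empty groups yield NA rows.
    """
    rows = {}
    for direction in ("up", "down"):
        sub = calls[calls["regulated"] == direction]
        rows[(direction, "siCt")] = _box_stats(sub["fc_ct"].to_numpy())
        rows[(direction, "siCHD8")] = _box_stats(sub["fc_kd"].to_numpy())
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["direction", "arm"])
    return out


def fold_induction(
    table: pd.DataFrame,
    vehicle: str = "EtOH",
) -> pd.Series:
    """Per-condition fold induction relative to the vehicle condition.

    ``table`` rows are individual measurements with a ``condition`` column
    and either ``target_cq`` + ``reference_cq`` (quantities then computed as
    ``2^-(Cq_target - Cq_reference)``, amplification efficiency fixed at 2)
    or a precomputed ``normalized`` column.  Fold = mean(normalized within
    condition) / mean(normalized within vehicle); the vehicle fold is 1 by
    construction.
    """
    if "condition" not in table.columns:
        raise ValueError("qPCR table needs a 'condition' column")
    if {"target_cq", "reference_cq"} <= set(table.columns):
        if table["target_cq"].isna().any() or table["reference_cq"].isna().any():
            raise ValueError("missing target or reference Cq measurement")
        norm = np.exp2(-(table["target_cq"] - table["reference_cq"]))
    elif "normalized" in table.columns:
        if table["normalized"].isna().any():
            raise ValueError("missing normalized measurement")
        norm = table["normalized"].astype(float)
    else:
        raise ValueError("qPCR table needs target_cq/reference_cq or normalized columns")
    by_cond = norm.groupby(table["condition"]).mean()
    if vehicle not in by_cond.index:
        raise ValueError(f"vehicle condition {vehicle!r} absent from table")
    return by_cond / by_cond[vehicle]
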