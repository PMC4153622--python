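"""Differential-expression calling against a reference population-doubling level.

The study design is a genes × samples log2-intensity matrix with an ordered
set of culture groups (PD 38, PD 47, PD 54; three biological replicates each).
Each non-reference group is contrasted against the reference (lowest-PD)
group.  A gene is called differentially expressed when it passes both

* a fold-change filter: log2 fold change strictly below ``-fc_thresh`` or
  strictly above ``+fc_thresh`` (default 0.4), and
* a significance filter: BH-adjusted q-value strictly below ``alpha``
  (default 0.05); a ``use_raw_p`` switch applies the raw p-value instead.

Per-gene significance uses a two-sided two-sample t-test.  The default is the
classical pooled-variance Student test (the comparison the study's statistics
section describes), which is exact under equal within-group variances — the
regime the synthetic generator produces — and therefore calibrated at n = 3;
the Welch unequal-variance variant is selectable but measurably conservative
at such small n.  Degenerate inputs follow explicit conventions: zero variance
on both sides gives p = 1 for equal means and p = 0 otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_FC_THRESH = 0.4
DEFAULT_ALPHA = 0.05


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values with per-sample group/replicate labels.

    ``values``: genes × samples DataFrame (index = gene ids, columns = sample
    ids).  ``samples``: DataFrame indexed by sample id with columns ``group``
    and ``replicate``, aligned to the value columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample sheet does not match matrix columns")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if "group" not in self.samples.columns:
            raise ValueError("sample sheet lacks a 'group' column")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.samples["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def group_values(self, group: str) -> pd.DataFrame:
        cols = self.samples.index[self.samples["group"] == group]
        if len(cols) == 0:
            raise ValueError(f"no samples in group {group!r}")
        return self.values[cols]

    def group_means(self) -> pd.DataFrame:
        """Genes × groups matrix of per-group mean expression."""
        return pd.DataFrame(
            {g: self.group_values(g).mean(axis=1) for g in self.groups}
        )


def log2_fold_change(
    matrix: ExpressionMatrix, group: str, reference: str
) -> pd.Series:
    """Per-gene mean(group) − mean(reference) on the log2 scale."""
    return (
        matrix.group_values(group).mean(axis=1)
        - matrix.group_values(reference).mean(axis=1)
    ).rename("log2fc")


def de_test(
    matrix: ExpressionMatrix, group: str, reference: str, method: str = "student"
) -> pd.Series:
    """Two-sided two-sample t-test p-value per gene, ``group`` vs ``reference``.

    ``method="student"`` (default) is the pooled-variance Student test;
    ``method="welch"`` is the unequal-variance Welch variant.  Zero variance
    on both sides: p = 1 when the means are equal, p = 0 when they differ
    (the observed difference is then noiseless).
    """
    if method not in ("student", "welch"):
        raise ValueError(f"unknown test method {method!r}")
    a = matrix.group_values(group).to_numpy(dtype=float)
    b = matrix.group_values(reference).to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("t-test needs >= 2 replicates per side")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant genes trip scipy's precision-loss warning; the
        # degenerate convention below handles them explicitly
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, axis=1, equal_var=(method == "student")).pvalue
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    return pd.Series(p, index=matrix.values.index, name="p_value")


def adjust_fdr(p_values: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini–Hochberg step-up q-values, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return pd.Series([], dtype=float, name="q_value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    index = p_values.index if isinstance(p_values, pd.Series) else None
    return pd.Series(np.clip(q, 0.0, 1.0), index=index, name="q_value")


def call_de(
    log2fc: pd.Series,
    p_or_q: pd.Series,
    fc_thresh: float = DEFAULT_FC_THRESH,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Apply the strict fold-change and significance thresholds.

    Both criteria are strict inequalities: |log2fc| must exceed ``fc_thresh``
    and the significance value must be below ``alpha``.  Direction is the sign
    of the fold change for called genes, ``"none"`` otherwise.
    """
    if not log2fc.index.equals(p_or_q.index):
        if set(log2fc.index) != set(p_or_q.index):
            raise ValueError("gene sets of log2fc and significance values differ")
        p_or_q = p_or_q.reindex(log2fc.index)
    passes_fc = (log2fc > fc_thresh) | (log2fc < -fc_thresh)
    passes_sig = p_or_q < alpha
    is_de = passes_fc & passes_sig
    direction = np.where(~is_de, "none", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {"log2fc": log2fc, "sig": p_or_q, "is_de": is_de, "direction": direction}
    )


def de_table(
    matrix: ExpressionMatrix,
    reference: str,
    fc_thresh: float = DEFAULT_FC_THRESH,
    alpha: float = DEFAULT_ALPHA,
    use_raw_p: bool = False,
    method: str = "student",
) -> pd.DataFrame:
    """Full DE table over every non-reference contrast.

    Columns: gene_id, contrast, log2fc, p, q, is_de, direction.  The
    significance filter uses BH q-values by default; ``use_raw_p`` switches to
    the raw per-gene p-value.  FDR adjustment is performed within each
    contrast.
    """
    if reference not in matrix.groups:
        raise ValueError(f"reference group {reference!r} absent from matrix")
    frames = []
    for group in matrix.groups:
        if group == reference:
            continue
        lfc = log2_fold_change(matrix, group, reference)
        p = de_test(matrix, group, reference, method)
        q = adjust_fdr(p)
        called = call_de(lfc, p if use_raw_p else q, fc_thresh, alpha)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": lfc.index,
                    "contrast": f"{group}_vs_{reference}",
                    "log2fc": lfc.to_numpy(),
                    "p": p.to_numpy(),
                    "q": q.to_numpy(),
                    "is_de": called["is_de"].to_numpy(),
                    "direction": called["direction"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def de_gene_set(table: pd.DataFrame, contrast: str | None = None) -> set[str]:
    """Gene ids called DE, optionally restricted to one contrast."""
    sub = table if contrast is None else table[table["contrast"] == contrast]
    return set(sub.loc[sub["is_de"], "gene_id"])


def overlap_fraction(de_set_a: set[str], de_set_b: set[str]) -> float:
    """|a ∩ b| / |a| — the fraction of set A's genes shared with set B."""
    if not de_set_a:
        raise ValueError("overlap fraction undefined for an empty first set")
    return len(de_set_a & de_set_b) / len(de_set_a)
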