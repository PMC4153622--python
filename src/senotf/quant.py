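"""Wet-lab quantification utilities: PD bookkeeping, qPCR NRQ, ChIP, blots.

Population doublings accumulate as ΔPD = log2(n_f / n_i) per subculture.
qPCR normalization follows the multi-reference relative-quantity model used
by qbase-style tools: technical replicates are averaged on the Ct scale,
relative quantities are RQ = E^(ΔCt), the normalization factor per sample is
the geometric mean of the reference-gene RQs, and NRQs are rescaled so the
calibrator group's mean is 1 per target.  Error bars propagate relative SDs
in quadrature (the product/quotient rule).  ChIP-qPCR supports fold-over-IgG
and percent-input.  Group comparisons use the classical pooled-variance
two-tailed Student t-test (contrast with the Welch test used for arrays).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------- PD ledger

def delta_pd(n_f: float, n_i: float) -> float:
    """Population doublings in one subculture: log2(n_f / n_i)."""
    if n_f <= 0 or n_i <= 0:
        raise ValueError("cell counts must be positive")
    return float(np.log2(n_f / n_i))


@dataclass
class CultureLog:
    """Time-ordered subculture records (passage, cells in, cells out)."""

    records: list[tuple[str, float, float]]
    initial_pd: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_pd < 0:
            raise ValueError("initial PD must be >= 0")
        for label, n_i, n_f in self.records:
            if n_i <= 0 or n_f <= 0:
                raise ValueError(f"non-positive cell count in passage {label!r}")


def cumulative_pd(log: CultureLog) -> pd.Series:
    """Running PD level after each subculture, starting from initial_pd.

    The final entry is the culture's PD level; an empty log yields the initial
    value alone (index ``"initial"``).
    """
    labels = ["initial"] + [r[0] for r in log.records]
    deltas = [0.0] + [delta_pd(n_f, n_i) for _, n_i, n_f in log.records]
    return pd.Series(log.initial_pd + np.cumsum(deltas), index=labels, name="pd")


# ---------------------------------------------------------------- qPCR NRQ

def relative_quantity(ct_calibrator: float, ct_sample: float, efficiency: float) -> float:
    """RQ = E^(ct_calibrator − ct_sample); one cycle earlier = E-fold more."""
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("amplification efficiency must lie in (1, 2]")
    return float(efficiency ** (ct_calibrator - ct_sample))


def propagate_sd(relative_sds: Sequence[float]) -> float:
    """Combined relative SD of a product/quotient: sqrt of the sum of squares."""
    sds = np.asarray(list(relative_sds), dtype=float)
    if (sds < 0).any():
        raise ValueError("relative SDs must be >= 0")
    return float(np.sqrt((sds ** 2).sum()))


def _tech_averaged(ct: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical replicates on the Ct scale (before exponentiation)."""
    required = {"sample_id", "group", "gene_id", "Ct", "efficiency"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns {sorted(missing)}")
    return (
        ct.groupby(["sample_id", "group", "gene_id"], sort=False)
        .agg(ct_mean=("Ct", "mean"), ct_sd=("Ct", "std"), efficiency=("efficiency", "first"))
        .reset_index()
    )


def normalize_nrq(
    ct: pd.DataFrame,
    targets: Sequence[str],
    reference_genes: Sequence[str],
    calibrator_group: str,
) -> pd.DataFrame:
    """Normalized relative quantities per (sample, target gene).

    Pipeline: technical replicates averaged on the Ct scale → per-gene RQ
    anchored at the calibrator-group mean Ct → NRQ = RQ / geometric mean of
    the reference-gene RQs of the same sample → per-target rescaling so the
    calibrator-group mean NRQ equals 1.  Per-sample loading factors shared by
    all genes cancel in the reference normalization.

    The reference-gene set is a required explicit argument.  A reference gene
    missing from any sample raises an error naming that sample.  Output
    columns: sample_id, group, gene_id, nrq, rel_sd (technical relative SD
    propagated through the quotient).
    """
    if not list(reference_genes):
        raise ValueError("need >= 1 reference gene")
    tech = _tech_averaged(ct)
    if calibrator_group not in set(tech["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent from table")
    for sid, sub in tech.groupby("sample_id", sort=False):
        missing = set(reference_genes) - set(sub["gene_id"])
        if missing:
            raise ValueError(
                f"reference gene(s) {sorted(missing)} missing in sample {sid!r}"
            )

    eff = tech.drop_duplicates("gene_id").set_index("gene_id")["efficiency"]
    anchor = (
        tech[tech["group"] == calibrator_group]
        .groupby("gene_id")["ct_mean"].mean()
    )
    tech = tech.assign(
        rq=[
            relative_quantity(anchor[g], c, eff[g])
            for g, c in zip(tech["gene_id"], tech["ct_mean"])
        ],
        # relative SD of RQ from the technical Ct scatter: ln(E)·sd(Ct)
        rq_rel_sd=[
            float(np.log(eff[g]) * (0.0 if np.isnan(s) else s))
            for g, s in zip(tech["gene_id"], tech["ct_sd"])
        ],
    )

    ref = tech[tech["gene_id"].isin(reference_genes)]
    nf = ref.groupby("sample_id").agg(
        nf=("rq", lambda v: float(np.exp(np.log(v).mean()))),
        nf_rel_sd=("rq_rel_sd", lambda v: propagate_sd(v) / len(v)),
    )

    out_rows = []
    for gene in targets:
        sub = tech[tech["gene_id"] == gene]
        if sub.empty:
            raise ValueError(f"target gene {gene!r} absent from Ct table")
        sub = sub.merge(nf, on="sample_id")
        nrq = sub["rq"] / sub["nf"]
        scale = nrq[sub["group"] == calibrator_group].mean()
        for (_, row), val in zip(sub.iterrows(), nrq / scale):
            out_rows.append(
                (
                    row["sample_id"], row["group"], gene, float(val),
                    propagate_sd([row["rq_rel_sd"], row["nf_rel_sd"]]),
                )
            )
    return pd.DataFrame(
        out_rows, columns=["sample_id", "group", "gene_id", "nrq", "rel_sd"]
    )


def reference_geomean_check(
    ct: pd.DataFrame, reference_genes: Sequence[str]
) -> pd.Series:
    """Per-sample geometric mean of normalized reference-gene quantities.

    Equals 1 (to float tolerance) by construction of the geometric-mean
    normalization factor; exposed so callers can assert the invariant.
    """
    tech = _tech_averaged(ct)
    eff = tech.drop_duplicates("gene_id").set_index("gene_id")["efficiency"]
    anchor = tech.groupby("gene_id")["ct_mean"].mean()
    tech = tech.assign(
        rq=[
            relative_quantity(anchor[g], c, eff[g])
            for g, c in zip(tech["gene_id"], tech["ct_mean"])
        ]
    )
    ref = tech[tech["gene_id"].isin(reference_genes)]
    nf = ref.groupby("sample_id")["rq"].apply(lambda v: float(np.exp(np.log(v).mean())))
    normalized = ref.assign(nrq=ref["rq"] / nf[ref["sample_id"]].to_numpy())
    return normalized.groupby("sample_id")["nrq"].apply(
        lambda v: float(np.exp(np.log(v).mean()))
    )


# ---------------------------------------------------------------- ChIP-qPCR

def chip_enrichment(
    ct_ip: float,
    ct_control: float,
    efficiency: float = 2.0,
    mode: str = "fold_over_control",
    input_dilution_factor: float = 1.0,
) -> float:
    """ChIP-qPCR signal relative to a control.

    ``fold_over_control``: E^(ct_control − ct_ip) with the IgG (mock) IP as
    control.  ``percent_input``: the control is an input aliquot diluted
    1/``input_dilution_factor``; its Ct is corrected by −log_E(dilution) and
    the recovery is expressed as a percentage, so equal Cts with a 1/100
    aliquot give 1% input.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("amplification efficiency must lie in (1, 2]")
    if mode == "fold_over_control":
        return float(efficiency ** (ct_control - ct_ip))
    if mode == "percent_input":
        if input_dilution_factor <= 0:
            raise ValueError("input dilution factor must be positive")
        adjusted = ct_control - np.log(input_dilution_factor) / np.log(efficiency)
        return float(100.0 * efficiency ** (adjusted - ct_ip))
    raise ValueError(f"unknown ChIP quantification mode {mode!r}")


# ------------------------------------------------------------- densitometry

def normalize_band(
    intensities: Sequence[float],
    loading_controls: Sequence[float],
    reference_ratios: Sequence[float] | None = None,
) -> np.ndarray:
    """Band intensity over loading control, rescaled to a reference-group mean.

    ``reference_ratios`` are the target/control ratios of the reference group
    (defaults to the input ratios themselves, i.e. normalization to their own
    mean).
    """
    target = np.asarray(intensities, dtype=float)
    control = np.asarray(loading_controls, dtype=float)
    if (control <= 0).any():
        raise ValueError("loading-control intensity must be positive")
    ratios = target / control
    ref = ratios if reference_ratios is None else np.asarray(reference_ratios, float)
    ref_mean = ref.mean()
    if ref_mean <= 0:
        raise ValueError("reference-group mean ratio must be positive")
    return ratios / ref_mean


# ------------------------------------------------------------------ t-test

def group_ttest(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-tailed pooled-variance Student t-test p-value.

    Degenerate variance convention: both groups constant → p = 1 when the
    means are equal, p = 0 otherwise.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if a.var() == 0 and b.var() == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=True).pvalue)
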