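"""Synthetic inputs with recorded ground truth.

Everything the pipeline consumes can be generated here: promoter sequences
(optionally with planted motif occurrences), replicate expression matrices
with a planted differentially-expressed fraction, qPCR Ct tables with known
fold changes, and subculture cell-count logs.  Each generator is deterministic
under the configuration seed, and the truth it plants (DE status, per-group
log2 fold changes, per-motif planted site counts) is returned explicitly so
downstream calls can be scored against it.

The default configuration mirrors the study design this package targets:
three culture groups at increasing population-doubling levels (PD38, PD47,
PD54), three biological replicates per group, 1,000-bp promoter windows, a
10% DE fraction with ±1 log2-unit shifts and 0.25 log2-units of replicate
noise (a clearly-detectable microarray effect over typical array noise).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .de import ExpressionMatrix
from .motifs import IUPAC_CODES, IUPACMotif, PromoterCollection

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults encode the emulated design: a 3-group × 3-replicate log-intensity
    matrix over ``n_genes`` genes, one 1,000-bp promoter per gene, and
    Poisson-distributed motif planting rates for targeted vs background
    promoters.
    """

    n_genes: int = 5000
    n_promoters: int = 5000
    promoter_length: int = 1000
    groups: tuple[str, ...] = ("PD38", "PD47", "PD54")
    replicates_per_group: int = 3
    de_fraction: float = 0.1
    effect_size: float = 1.0
    noise_sd: float = 0.25
    gc_content: float = 0.45
    plant_rate_target: float = 2.0
    plant_rate_background: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_promoters", "promoter_length", "replicates_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")
        if self.plant_rate_target < 0 or self.plant_rate_background < 0:
            raise ValueError("planting rates must be non-negative")
        if len(self.groups) < 2:
            raise ValueError("need a reference group plus >= 1 test group")
        object.__setattr__(self, "groups", tuple(self.groups))

    @property
    def reference_group(self) -> str:
        return self.groups[0]

    @property
    def n_de(self) -> int:
        """Planted DE gene count: round-half-to-even of de_fraction·n_genes."""
        return round(self.de_fraction * self.n_genes)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# Disjoint substreams per generator so adding one stage never reshuffles another.
_STREAMS = {"promoters": 1, "plant": 2, "expression": 3, "ct": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def generate_promoters(config: SimulationConfig) -> PromoterCollection:
    """I.i.d. promoter sequences with P(G) = P(C) = gc_content / 2."""
    rng = _rng(config.seed, "promoters")
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    draws = rng.choice(4, size=(config.n_promoters, config.promoter_length), p=probs)
    seqs = _BASES[draws]
    return PromoterCollection(
        {
            gid: seqs[i].tobytes().decode("ascii")
            for i, gid in enumerate(gene_ids(config.n_promoters))
        }
    )


def plant_motif(
    promoters: PromoterCollection,
    motif: IUPACMotif,
    target_ids: set[str],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[PromoterCollection, dict[str, int]]:
    """Write concrete motif variants into promoters at Poisson-random counts.

    Targets receive ``Poisson(plant_rate_target)`` sites, all other promoters
    ``Poisson(plant_rate_background)``; each site is a uniformly sampled
    concrete variant (sampled per position, so even ineligible motifs are
    plantable) written at a uniformly chosen position that does not overlap a
    previously planted site.  Sites that cannot be placed without overlap are
    dropped and the *actual* planted count is recorded.  Sequence lengths are
    never changed.

    Returns the modified collection and the per-promoter planted counts.
    """
    m = len(motif.pattern)
    unknown = target_ids - set(promoters.ids)
    if unknown:
        raise ValueError(f"target ids absent from promoters: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed,
                               spawn_key=(_STREAMS["plant"],))
    )
    planted: dict[str, int] = {}
    out = {}
    for gid, seq in promoters.items():
        if m >= len(seq):
            raise ValueError(f"motif longer than promoter {gid!r}")
        rate = config.plant_rate_target if gid in target_ids else config.plant_rate_background
        k = int(rng.poisson(rate))
        placed: list[int] = []
        chars = list(seq)
        attempts = 0
        while len(placed) < k and attempts < 100 * max(k, 1):
            attempts += 1
            pos = int(rng.integers(0, len(seq) - m + 1))
            if any(pos < p + m and p < pos + m for p in placed):
                continue
            variant = "".join(
                IUPAC_CODES[c][rng.integers(0, len(IUPAC_CODES[c]))] for c in motif.pattern
            )
            chars[pos:pos + m] = variant
            placed.append(pos)
        out[gid] = "".join(chars)
        planted[gid] = len(placed)
    return PromoterCollection(out), planted


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Replicate log2-intensity matrix with a planted DE structure.

    Per-gene reference-group means are drawn from N(8, 2²) — a typical array
    log-intensity range.  A round-half-to-even fraction ``de_fraction`` of
    genes is truly DE: each receives a random sign and a ±``effect_size``
    shift in every non-reference group.  I.i.d. N(0, noise_sd²) noise is added
    to every observation.

    Returns the matrix and a truth table with one row per gene: ``is_de``,
    the true log2 fold change per non-reference group, and the sign.
    """
    rng = _rng(config.seed, "expression")
    ids = gene_ids(config.n_genes)
    baseline = rng.normal(8.0, 2.0, size=config.n_genes)
    n_de = config.n_de
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    is_de = np.zeros(config.n_genes, dtype=bool)
    is_de[de_idx] = True
    signs = np.where(rng.random(config.n_genes) < 0.5, -1.0, 1.0)
    signs[~is_de] = 0.0

    columns: dict[str, np.ndarray] = {}
    sample_rows = []
    for group in config.groups:
        shift = 0.0 if group == config.reference_group else signs * config.effect_size
        for rep in range(1, config.replicates_per_group + 1):
            sid = f"{group}_r{rep}"
            noise = rng.normal(0.0, config.noise_sd, size=config.n_genes) \
                if config.noise_sd > 0 else 0.0
            columns[sid] = baseline + shift + noise
            sample_rows.append((sid, group, rep))
    values = pd.DataFrame(columns, index=pd.Index(ids, name="gene_id"))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "group", "replicate"]
    ).set_index("sample_id")

    truth = pd.DataFrame({"gene_id": ids, "is_de": is_de, "sign": signs.astype(int)})
    for group in config.groups[1:]:
        truth[f"true_log2fc_{group}"] = signs * config.effect_size
    return ExpressionMatrix(values, samples), truth.set_index("gene_id")


def generate_ct_table(
    true_fold_changes: dict[str, dict[str, float]],
    reference_genes: list[str],
    efficiencies: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    groups: tuple[str, ...] = ("PD38", "PD47", "PD54"),
    n_bio: int = 3,
    n_tech: int = 2,
) -> pd.DataFrame:
    """qPCR Ct table with known ground-truth fold changes.

    ``true_fold_changes`` maps target gene → {non-calibrator group → fold};
    the first group is the calibrator (fold 1) and reference genes have fold 1
    everywhere by construction.  Ct values satisfy quantity = E^(−Ct) up to a
    per-sample loading factor shared by all genes of that sample, plus
    Gaussian Ct noise with sd ``noise_sd``.

    Columns: sample_id, group, gene_id, replicate_bio, replicate_tech, Ct,
    efficiency.
    """
    if not reference_genes:
        raise ValueError("need >= 1 reference gene")
    genes = list(true_fold_changes) + [g for g in reference_genes
                                       if g not in true_fold_changes]
    for g in genes:
        e = efficiencies.get(g)
        if e is None or not 1.0 < e <= 2.0:
            raise ValueError(f"efficiency for {g!r} must lie in (1, 2]")
    for g, folds in true_fold_changes.items():
        for grp, f in folds.items():
            if f <= 0:
                raise ValueError(f"non-positive fold change for {g!r} in {grp!r}")
    rng = _rng(seed, "ct")
    base_ct = {g: float(rng.uniform(20.0, 28.0)) for g in genes}
    rows = []
    for group in groups:
        for bio in range(1, n_bio + 1):
            sid = f"{group}_b{bio}"
            loading = float(rng.lognormal(0.0, 0.1))
            for g in genes:
                fold = 1.0
                if g in true_fold_changes and group != groups[0]:
                    fold = true_fold_changes[g].get(group, 1.0)
                e = efficiencies[g]
                # quantity = e**(-base_ct) * fold * loading; Ct = -log_E(quantity)
                ct_true = base_ct[g] - (np.log(fold) + np.log(loading)) / np.log(e)
                for tech in range(1, n_tech + 1):
                    noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
                    rows.append((sid, group, g, bio, tech, ct_true + noise, e))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "gene_id", "replicate_bio",
                 "replicate_tech", "Ct", "efficiency"],
    )


def generate_culture_log(
    n_subcultures: int = 5,
    initial_pd: float = 19.0,
    mean_delta_pd: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Subculture cell-count log with known per-passage doubling truth.

    Inoculum sizes are drawn around 5×10⁵ cells; final counts realise a
    per-passage ΔPD near ``mean_delta_pd``.  Columns: passage, n_inoculated,
    n_final; the true cumulative PD is initial_pd + Σ log2(n_f/n_i).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(1, n_subcultures + 1):
        n_i = float(rng.uniform(3e5, 8e5))
        delta = float(rng.normal(mean_delta_pd, 0.3))
        rows.append((f"P{i}", n_i, n_i * 2.0 ** delta))
    df = pd.DataFrame(rows, columns=["passage", "n_inoculated", "n_final"])
    df.attrs["initial_pd"] = initial_pd
    return df
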