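"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Emulates a paired two-arm intervention design: two arms of subjects
(default 10 per arm, mirroring a 10-performer / 10-control study), each
sampled immediately before and after a two-hour session, with
negative-binomial miRNA counts carrying subject (pair) effects and a
planted condition:time interaction in a minority of miRNAs.  Also
generates predicted/validated miRNA-target tables whose conservation and
score distributions straddle the downstream filter thresholds, and a
pair of annotation universes (default sizes matching the zebra finch
17,926 and human 20,219 annotated gene counts) linked by a many-to-one
ortholog map with a plantable overlap signal.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "SimParams",
    "SimTruth",
    "TargetScoreParams",
    "UniversePair",
    "simulate_paired_counts",
    "simulate_target_tables",
    "simulate_universe_pair",
]

FAMILY_CLASSES = ("conserved", "broadly_conserved", "poorly_conserved", "other")
SITE_CLASSES = ("conserved", "nonconserved", "non_canonical")
EVIDENCE_STRONG = ("reporter_assay", "western_blot")


@dataclass(frozen=True)
class SimParams:
    """Parameters of the paired NB count simulation.

    The per-gene model for sample s of subject p(s) is

        K ~ NB(mean = sf_s * 2**eta, dispersion = alpha_g)
        eta = mu_g + pair_p + time_lfc * I(post) + beta_g * I(performance) * I(post)

    where beta_g is nonzero (random sign, |beta_g| uniform on
    ``interaction_lfc_range``) for exactly ``round(frac_de * n_mirnas)``
    miRNAs and the dispersion follows the trend ``alpha = a0/mu + a1``.
    """

    n_mirnas: int = 1000
    n_pairs_per_arm: int = 10
    baseline_log2_mean_range: tuple[float, float] = (3.0, 10.0)
    pair_effect_sd: float = 0.5
    dispersion_trend: tuple[float, float] = (3.0, 0.05)
    frac_de: float = 0.05
    interaction_lfc_range: tuple[float, float] = (1.0, 1.5)
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    time_lfc: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas <= 0 or self.n_pairs_per_arm <= 0:
            raise ValidationError("n_mirnas and n_pairs_per_arm must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValidationError("frac_de must lie in [0, 1]")
        for name in ("baseline_log2_mean_range", "interaction_lfc_range", "size_factor_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} must have lower <= upper, got ({lo}, {hi})")
        a0, a1 = self.dispersion_trend
        if a0 < 0 or a1 < 0:
            raise ValidationError("dispersion trend coefficients must be non-negative")
        if self.size_factor_range[0] <= 0:
            raise ValidationError("size factors must be positive")


@dataclass(frozen=True)
class SimTruth:
    """Planted quantities, recoverable without re-simulation."""

    de_ids: tuple[str, ...]
    true_interaction_lfc: dict[str, float]
    true_size_factors: dict[str, float]
    true_dispersions: dict[str, float]


def simulate_paired_counts(params: SimParams):
    """Simulate the paired 2x2 design: counts, sample sheet and planted truth.

    Returns ``(counts, sheet, truth)`` where ``counts`` is an integer
    miRNA x sample DataFrame aligned with ``sheet`` (columns sample_id,
    pair_id, condition, time; 4 * n_pairs_per_arm samples).
    """
    rng = np.random.default_rng(params.seed)
    n_g = params.n_mirnas
    n_pairs = params.n_pairs_per_arm

    mirna_ids = [f"sim-miR-{i + 1:05d}" for i in range(n_g)]
    rows = []
    for cond, prefix in (("performance", "P"), ("control", "C")):
        for j in range(n_pairs):
            pid = f"{prefix}{j + 1:02d}"
            for time in ("pre", "post"):
                rows.append((f"{pid}_{time}", pid, cond, time))
    sheet = pd.DataFrame(rows, columns=["sample_id", "pair_id", "condition", "time"])

    lo, hi = params.baseline_log2_mean_range
    mu_log2 = rng.uniform(lo, hi, size=n_g)
    a0, a1 = params.dispersion_trend
    alpha = a0 / (2.0**mu_log2) + a1

    n_de = round(params.frac_de * n_g)
    de_idx = rng.choice(n_g, size=n_de, replace=False)
    beta = np.zeros(n_g)
    if n_de:
        mag = rng.uniform(*params.interaction_lfc_range, size=n_de)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        beta[de_idx] = sign * mag

    pair_ids = list(dict.fromkeys(sheet["pair_id"]))
    pair_eff = dict(zip(pair_ids, rng.normal(0.0, params.pair_effect_sd, size=len(pair_ids))))
    sf = rng.uniform(*params.size_factor_range, size=len(sheet))

    post = (sheet["time"] == "post").to_numpy(dtype=float)
    perf = (sheet["condition"] == "performance").to_numpy(dtype=float)
    pair_vec = sheet["pair_id"].map(pair_eff).to_numpy(dtype=float)

    # log2-scale linear predictor, genes x samples
    eta = (
        mu_log2[:, None]
        + pair_vec[None, :]
        + params.time_lfc * post[None, :]
        + beta[:, None] * (perf * post)[None, :]
    )
    mean = sf[None, :] * 2.0**eta
    r = 1.0 / alpha[:, None]
    counts = rng.negative_binomial(r, r / (r + mean))

    counts_df = pd.DataFrame(counts, index=mirna_ids, columns=sheet["sample_id"].tolist())
    counts_df.index.name = "mirna_id"
    de_ids = tuple(mirna_ids[i] for i in sorted(de_idx))
    truth = SimTruth(
        de_ids=de_ids,
        true_interaction_lfc={mirna_ids[i]: float(beta[i]) for i in sorted(de_idx)},
        true_size_factors=dict(zip(sheet["sample_id"], sf.astype(float))),
        true_dispersions=dict(zip(mirna_ids, alpha.astype(float))),
    )
    return counts_df, sheet, truth


@dataclass(frozen=True)
class TargetScoreParams:
    """Score distributions for synthetic predicted-target tables.

    Defaults straddle the downstream filter thresholds (PCT 0.2,
    context++ -0.15) so both sides of every boundary are populated.
    """

    pct_beta: tuple[float, float] = (1.2, 3.0)
    contextpp_mean: float = -0.15
    contextpp_sd: float = 0.15
    family_probs: tuple[float, ...] = (0.35, 0.25, 0.3, 0.1)
    site_probs: tuple[float, ...] = (0.5, 0.35, 0.15)
    predicted_per_mirna: int = 30
    validated_per_mirna: int = 5
    evidence_probs: tuple[float, ...] = (0.4, 0.3, 0.3)  # reporter, western, weak


def simulate_target_tables(
    n_mirnas: int,
    n_genes: int,
    score_params: TargetScoreParams | None = None,
    seed: int = 0,
):
    """Synthetic predicted and validated miRNA-target tables.

    Returns ``(predicted, validated)`` DataFrames with the column layout
    of the target-filtering stage.  Scores are drawn independently of the
    categorical annotations.
    """
    if n_mirnas < 0 or n_genes < 0:
        raise ValidationError("n_mirnas and n_genes must be non-negative")
    sp = score_params or TargetScoreParams()
    rng = np.random.default_rng(seed)
    mirnas = [f"sim-miR-{i + 1:05d}" for i in range(n_mirnas)]
    genes = [f"GENE{i + 1:06d}" for i in range(n_genes)]

    cols_pred = ["mirna_id", "family_class", "gene_id", "site_class", "pct", "contextpp",
                 "source", "evidence"]
    if n_mirnas == 0 or n_genes == 0:
        empty = pd.DataFrame(columns=cols_pred)
        return empty, empty.copy()

    n_pred = n_mirnas * sp.predicted_per_mirna
    pred = pd.DataFrame(
        {
            "mirna_id": np.repeat(mirnas, sp.predicted_per_mirna),
            "family_class": rng.choice(FAMILY_CLASSES, size=n_pred, p=sp.family_probs),
            "gene_id": rng.choice(genes, size=n_pred),
            "site_class": rng.choice(SITE_CLASSES, size=n_pred, p=sp.site_probs),
            "pct": rng.beta(*sp.pct_beta, size=n_pred),
            "contextpp": np.clip(
                rng.normal(sp.contextpp_mean, sp.contextpp_sd, size=n_pred), -1.0, 0.2
            ),
            "source": "predicted",
            "evidence": "none",
        }
    )
    pred = pred.drop_duplicates(subset=["mirna_id", "gene_id"]).reset_index(drop=True)

    n_val = n_mirnas * sp.validated_per_mirna
    val = pd.DataFrame(
        {
            "mirna_id": np.repeat(mirnas, sp.validated_per_mirna),
            "family_class": rng.choice(FAMILY_CLASSES, size=n_val, p=sp.family_probs),
            "gene_id": rng.choice(genes, size=n_val),
            "site_class": rng.choice(SITE_CLASSES[:2], size=n_val),
            "pct": np.nan,
            "contextpp": np.nan,
            "source": "validated",
            "evidence": rng.choice(
                ("reporter_assay", "western_blot", "weak"), size=n_val, p=sp.evidence_probs
            ),
        }
    )
    val = val.drop_duplicates(subset=["mirna_id", "gene_id"]).reset_index(drop=True)
    return pred, val


@dataclass(frozen=True)
class UniversePair:
    """Two species' gene universes, an ortholog map, and one set in each.

    The mapped intersection of ``set_a`` with ``set_b`` equals
    ``planted_overlap`` exactly by construction.
    """

    universe_a: tuple[str, ...]
    universe_b: tuple[str, ...]
    ortholog_map: dict[str, str]
    set_a: frozenset[str]
    set_b: frozenset[str]
    planted_overlap: int


def simulate_universe_pair(
    size_a: int = 17_926,
    size_b: int = 20_219,
    set_sizes: tuple[int, int] = (100, 100),
    planted_overlap: int = 25,
    seed: int = 0,
    mapped_fraction: float = 0.9,
) -> UniversePair:
    """Construct two universes with a many-to-one ortholog map and sets
    whose mapped intersection is exactly ``planted_overlap``.

    ``mapped_fraction`` controls ortholog coverage of universe A (the
    remainder stays unmapped, as real cross-species annotations do).
    """
    k_a, k_b = set_sizes
    if planted_overlap < 0 or planted_overlap > min(k_a, k_b):
        raise ValidationError(
            f"planted_overlap {planted_overlap} infeasible for set sizes {set_sizes}"
        )
    if k_a > size_a or k_b > size_b:
        raise ValidationError("set sizes cannot exceed universe sizes")
    if not 0.0 <= mapped_fraction <= 1.0:
        raise ValidationError("mapped_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    universe_a = tuple(f"TGU{i + 1:06d}" for i in range(size_a))
    universe_b = tuple(f"HSA{i + 1:06d}" for i in range(size_b))

    n_mapped = int(round(mapped_fraction * size_a))
    mapped_idx = rng.choice(size_a, size=n_mapped, replace=False)
    targets = rng.choice(size_b, size=n_mapped, replace=True)  # many-to-one allowed
    omap = {universe_a[i]: universe_b[t] for i, t in zip(mapped_idx, targets)}

    # core: planted_overlap A-genes with pairwise-distinct images
    core_a: list[str] = []
    core_b: list[str] = []
    seen_b: set[str] = set()
    order = rng.permutation(n_mapped)
    for j in order:
        if len(core_a) == planted_overlap:
            break
        g = universe_a[mapped_idx[j]]
        tgt = omap[g]
        if tgt not in seen_b:
            core_a.append(g)
            seen_b.add(tgt)
            core_b.append(tgt)
    if len(core_a) < planted_overlap:
        raise ValidationError("ortholog map too sparse to plant the requested overlap")

    core_b_set = set(core_b)
    # set_a fillers: unmapped genes or genes whose image avoids the core
    filler_pool_a = [
        g for g in universe_a
        if g not in core_a and omap.get(g) not in core_b_set
    ]
    n_fill_a = k_a - planted_overlap
    if n_fill_a > len(filler_pool_a):
        raise ValidationError("not enough universe-A genes outside the planted core")
    fill_a = [filler_pool_a[i] for i in rng.choice(len(filler_pool_a), n_fill_a, replace=False)]
    set_a = frozenset(core_a) | frozenset(fill_a)

    image_a = {omap[g] for g in set_a if g in omap}
    filler_pool_b = [g for g in universe_b if g not in image_a]
    n_fill_b = k_b - planted_overlap
    if n_fill_b > len(filler_pool_b):
        raise ValidationError("not enough universe-B genes outside the mapped image")
    fill_b = [filler_pool_b[i] for i in rng.choice(len(filler_pool_b), n_fill_b, replace=False)]
    set_b = frozenset(core_b) | frozenset(fill_b)

    return UniversePair(
        universe_a=universe_a,
        universe_b=universe_b,
        ortholog_map=omap,
        set_a=set_a,
        set_b=set_b,
        planted_overlap=planted_overlap,
    )
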