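"""Ground-truth generators for every pipeline input.

The generator emulates a two-model (AB1 mesothelioma, Renca renal cell
carcinoma), four-timepoint (days 0/2/4/6 relative to checkpoint-blockade
start), two-arm (responder / non-responder) bulk time-course design with an
embedded TF→target regulatory structure and five expression archetypes:

``on_fast_off``
    High at/near treatment start in responders and shut down by the end of
    the course (AB1 peaks at day 0, Renca at day 2); slow monotone rise in
    non-responders. Interferon-related TFs and the fast ISGs they drive.
``grad_up`` / ``grad_down``
    Gradual monotone rise / fall, identical in both arms.
``grad_up_resp``
    Gradual rise in responders only; flat-low in non-responders.
``flat``
    Constant mean; pure replicate noise.

Regulator→target coupling: a target's log-mean is an affine combination of
its regulators' log-means with weights U(0.5, 1.5), then rescaled so the
gene's peak mean (over arms, models and timepoints) equals its drawn peak
count. Counts are negative-binomial (gamma–Poisson) around mean × library
factor. All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from onoffgrn.containers import ExpressionMatrix
from onoffgrn.direct import DEFAULT_IFN_TFS, promoter_window
from onoffgrn.outcomes import GrowthCurve, PowerSpec

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_timecourse",
    "noiseless_means",
    "ground_truth",
    "simulate_annotations",
    "simulate_mixtures",
    "simulate_growth_curves",
    "simulate_survival",
    "simulate_velocity_embedding",
    "nb_counts",
]

ARCHETYPES = ("on_fast_off", "grad_up", "grad_up_resp", "grad_down", "flat")

# Four-point templates as fractions of peak mean, per arm. The on/fast-off
# responder template is model-specific: AB1 peaks at the first design
# timepoint, Renca one step later.
DEFAULT_TEMPLATES: dict = {
    "on_fast_off": {
        "responder": {"AB1": (1.0, 0.9, 0.3, 0.15), "Renca": (0.85, 1.0, 0.35, 0.15)},
        "non_responder": (0.2, 0.4, 0.6, 0.8),
    },
    "grad_up": {"responder": (0.15, 0.4, 0.7, 1.0), "non_responder": (0.15, 0.4, 0.7, 1.0)},
    "grad_up_resp": {"responder": (0.15, 0.4, 0.7, 1.0), "non_responder": (0.18, 0.2, 0.22, 0.24)},
    "grad_down": {"responder": (1.0, 0.6, 0.35, 0.2), "non_responder": (1.0, 0.6, 0.35, 0.2)},
    "flat": {"responder": (0.6, 0.6, 0.6, 0.6), "non_responder": (0.6, 0.6, 0.6, 0.6)},
}

_NONIFN_CYCLE = ("grad_up", "grad_down", "grad_up_resp", "flat")
DE_ARCHETYPES = ("on_fast_off", "grad_up_resp")


@dataclass
class SimConfig:
    """Design and noise parameters for the time-course generator."""

    n_genes: int = 300
    n_tfs: int = 10
    n_isg_fast: int = 40
    n_isg_slow: int = 40
    timepoints: tuple = (0, 2, 4, 6)
    replicates_per_cell: int = 3
    models: tuple = ("AB1", "Renca")
    dispersion: float = 0.15
    libsize_range: tuple = (0.7, 1.3)
    seed: int = 0
    flat_fraction: float = 0.2  # share of unassigned genes left as flat background
    peak_log_mean: float = 5.7  # median peak count ≈ 300
    peak_log_sd: float = 0.7
    templates: dict = field(default_factory=lambda: DEFAULT_TEMPLATES)

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_tfs <= 0:
            raise ValueError("n_genes and n_tfs must be positive")
        if self.n_tfs >= self.n_genes:
            raise ValueError("n_tfs must be < n_genes")
        if self.n_isg_fast + self.n_isg_slow > self.n_genes - self.n_tfs:
            raise ValueError("ISG counts exceed available non-TF genes")
        tps = tuple(self.timepoints)
        if len(tps) < 2 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        lo, hi = self.libsize_range
        if lo <= 0 or hi < lo:
            raise ValueError("libsize_range must be a positive interval")
        for arch, arms in self.templates.items():
            for arm, tpl in arms.items():
                tpls = tpl.values() if isinstance(tpl, Mapping) else [tpl]
                for t in tpls:
                    if len(t) != len(tps):
                        raise ValueError(f"template {arch}/{arm} length != {len(tps)} timepoints")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    genes: tuple
    tfs: tuple
    ifn_tfs: tuple
    true_edges: frozenset  # (regulator, target)
    direct_edges: frozenset  # promoter-proximal subset
    archetype_of_gene: dict
    de_genes: frozenset
    fast_isg_genes: frozenset
    isg_sets: dict  # gene-set name -> tuple of members (alpha/beta, gamma)
    edge_weights: dict  # (regulator, target) -> weight
    peaks: dict  # gene -> peak mean count

    def __post_init__(self) -> None:
        if not self.direct_edges <= self.true_edges:
            raise ValueError("direct_edges must be a subset of true_edges")
        fast = frozenset(g for g, a in self.archetype_of_gene.items() if a == "on_fast_off")
        if self.fast_isg_genes != fast:
            raise ValueError("fast_isg_genes must equal the on_fast_off archetype genes")

    @property
    def isg_genes(self) -> frozenset:
        return frozenset(g for members in self.isg_sets.values() for g in members)


def _template(cfg: SimConfig, archetype: str, arm: str, model: str) -> np.ndarray:
    tpl = cfg.templates[archetype][arm]
    if isinstance(tpl, Mapping):
        tpl = tpl.get(model, next(iter(tpl.values())))
    return np.asarray(tpl, dtype=float)


def _seed_pair(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    s_truth, s_noise = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(s_truth), np.random.default_rng(s_noise)


def ground_truth(config: SimConfig) -> GroundTruth:
    """Deterministic regulatory/dynamic ground truth for ``config``."""
    rng, _ = _seed_pair(config.seed)
    n_ifn = min(len(DEFAULT_IFN_TFS), config.n_tfs)
    ifn_tfs = list(DEFAULT_IFN_TFS[:n_ifn])
    other_tfs = [f"Tf{i:02d}" for i in range(n_ifn + 1, config.n_tfs + 1)]
    tfs = ifn_tfs + other_tfs

    archetype: dict[str, str] = {}
    for tf in ifn_tfs:
        archetype[tf] = "on_fast_off"
    for i, tf in enumerate(other_tfs):
        archetype[tf] = _NONIFN_CYCLE[i % len(_NONIFN_CYCLE)]

    n_targets = config.n_genes - config.n_tfs
    fast = [f"IsgF{i:03d}" for i in range(1, config.n_isg_fast + 1)]
    slow = [f"IsgS{i:03d}" for i in range(1, config.n_isg_slow + 1)]
    n_rest = n_targets - len(fast) - len(slow)
    n_flat = int(round(config.flat_fraction * n_rest))
    others = [f"G{i:04d}" for i in range(1, n_rest - n_flat + 1)]
    flats = [f"Bg{i:04d}" for i in range(1, n_flat + 1)]
    genes = tfs + fast + slow + others + flats

    edges: set[tuple[str, str]] = set()
    direct: set[tuple[str, str]] = set()
    weights: dict[tuple[str, str], float] = {}

    for g in fast:
        archetype[g] = "on_fast_off"
        n_reg = int(rng.integers(1, 3))  # 1 or 2 interferon TFs
        regs = rng.choice(ifn_tfs, size=min(n_reg, len(ifn_tfs)), replace=False)
        for r in regs:
            edges.add((r, g))
            direct.add((r, g))  # all fast-ISG edges are promoter-proximal
            weights[(r, g)] = float(rng.uniform(0.5, 1.5))

    grad_up_tfs = [t for t in other_tfs if archetype[t] == "grad_up"] or other_tfs or ifn_tfs
    for g in slow:
        archetype[g] = "grad_up"
        r = str(rng.choice(grad_up_tfs))
        edges.add((r, g))
        weights[(r, g)] = float(rng.uniform(0.5, 1.5))
        if rng.uniform() < 0.5:
            direct.add((r, g))

    pool = other_tfs or ifn_tfs
    for g in others:
        r = str(rng.choice(pool))
        archetype[g] = archetype[r]
        edges.add((r, g))
        weights[(r, g)] = float(rng.uniform(0.5, 1.5))
        if rng.uniform() < 0.5:
            direct.add((r, g))

    for g in flats:
        archetype[g] = "flat"

    peaks = {g: float(np.exp(rng.normal(config.peak_log_mean, config.peak_log_sd))) for g in genes}

    # ISG class assignment: the hallmark-style sets cover the fast ISGs,
    # their interferon TFs (themselves ISGs) and the slow chronic ISGs.
    isg_members = ifn_tfs + fast + slow
    classes = rng.choice(["alpha_beta", "gamma", "both"], size=len(isg_members), p=[0.35, 0.35, 0.3])
    ab = tuple(g for g, c in zip(isg_members, classes) if c in ("alpha_beta", "both"))
    gm = tuple(g for g, c in zip(isg_members, classes) if c in ("gamma", "both"))

    de = frozenset(g for g, a in archetype.items() if a in DE_ARCHETYPES)
    return GroundTruth(
        genes=tuple(genes),
        tfs=tuple(tfs),
        ifn_tfs=tuple(ifn_tfs),
        true_edges=frozenset(edges),
        direct_edges=frozenset(direct),
        archetype_of_gene=archetype,
        de_genes=de,
        fast_isg_genes=frozenset(g for g, a in archetype.items() if a == "on_fast_off"),
        isg_sets={"IFN_ALPHA_BETA": ab, "IFN_GAMMA": gm},
        edge_weights=weights,
        peaks=peaks,
    )


def noiseless_means(config: SimConfig, truth: GroundTruth | None = None) -> dict:
    """Mean count matrices (genes × timepoints) keyed by (model, response).

    TF means follow their archetype template scaled to the gene's peak;
    target log-means are the weighted sum of their regulators' log-means,
    rescaled so the target's maximum over all conditions equals its peak.
    """
    if truth is None:
        truth = ground_truth(config)
    tps = list(config.timepoints)
    conditions = [(m, r) for m in config.models for r in ("responder", "non_responder")]

    regs_of: dict[str, list[str]] = {}
    for r, t in truth.true_edges:
        regs_of.setdefault(t, []).append(r)
    for t in regs_of:
        regs_of[t].sort()

    out = {cond: pd.DataFrame(0.0, index=list(truth.genes), columns=tps) for cond in conditions}
    log_u: dict[str, dict] = {}
    for g in truth.genes:
        regs = regs_of.get(g)
        if regs:  # target: combine regulator shapes in log space
            per_cond = {}
            for model, resp in conditions:
                u = np.zeros(len(tps))
                for r in regs:
                    shape = _template(config, truth.archetype_of_gene[r], resp, model)
                    u += truth.edge_weights[(r, g)] * np.log(shape)
                per_cond[(model, resp)] = u
            log_u[g] = per_cond
        else:
            per_cond = {
                (model, resp): np.log(_template(config, truth.archetype_of_gene[g], resp, model))
                for model, resp in conditions
            }
            log_u[g] = per_cond

    for g in truth.genes:
        peak_log = max(u.max() for u in log_u[g].values())
        for cond in conditions:
            out[cond].loc[g] = truth.peaks[g] * np.exp(log_u[g][cond] - peak_log)
    return out


def nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma–Poisson (negative binomial) draw with var = μ + dispersion·μ²."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_timecourse(config: SimConfig):
    """Draw the full design: counts matrix, sample metadata, ground truth.

    Sample ids are ``{model}_{R|NR}_d{day}_r{rep}``; one mouse per sample
    (tumours are resected, so timepoints are cross-sectional).
    """
    truth = ground_truth(config)
    means = noiseless_means(config, truth)
    _, rng = _seed_pair(config.seed)

    lo, hi = config.libsize_range
    cols = {}
    meta_rows = []
    for model in config.models:
        for resp, tag in (("responder", "R"), ("non_responder", "NR")):
            block = means[(model, resp)]
            for day in config.timepoints:
                mu = block[day].to_numpy()
                for rep in range(1, config.replicates_per_cell + 1):
                    lf = rng.uniform(lo, hi)
                    sid = f"{model}_{tag}_d{day}_r{rep}"
                    cols[sid] = nb_counts(mu * lf, config.dispersion, rng)
                    meta_rows.append(
                        {"sample_id": sid, "model": model, "timepoint_day": day,
                         "response": resp, "mouse_id": f"m_{sid}"}
                    )
    matrix = ExpressionMatrix(pd.DataFrame(cols, index=list(truth.genes)), layer="counts")
    meta = pd.DataFrame(meta_rows)
    return matrix, meta, truth


def simulate_annotations(
    truth: GroundTruth,
    window_up: int = 400,
    window_down: int = 300,
    seed: int = 0,
    *,
    site_width: int = 10,
    gene_spacing: int = 50_000,
    chrom: str = "chr1",
):
    """TSS and TFBS tables consistent with the truth's direct-edge flags.

    Genes sit on one synthetic chromosome every ``gene_spacing`` bp on
    alternating strands. Every direct edge (TF, G) gets one binding site
    uniformly inside G's strand-aware promoter window; every indirect true
    edge gets a decoy site 2–5 kb away from G's TSS (outside any window),
    so window-based pruning recovers exactly the direct edges.
    """
    rng = np.random.default_rng(seed)
    tss_rows = []
    pos_of: dict[str, tuple[int, str]] = {}
    for i, g in enumerate(truth.genes):
        pos = gene_spacing * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        pos_of[g] = (pos, strand)
        tss_rows.append({"gene": g, "chrom": chrom, "tss": pos, "strand": strand})

    tfbs_rows = []
    for r, t in sorted(truth.true_edges):
        pos, strand = pos_of[t]
        if (r, t) in truth.direct_edges:
            w0, w1 = promoter_window(pos, strand, window_up, window_down)
            start = int(rng.integers(w0, w1 - site_width))
        else:
            offset = int(rng.integers(2000, 5000))
            side = 1 if rng.uniform() < 0.5 else -1
            start = pos + side * offset
        tfbs_rows.append({"tf": r, "chrom": chrom, "start": start, "end": start + site_width})

    return pd.DataFrame(tss_rows), pd.DataFrame(tfbs_rows)


def simulate_mixtures(
    reference: pd.DataFrame,
    proportions: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Linear mixtures of reference columns plus 0-truncated Gaussian noise.

    ``reference`` is genes × populations, ``proportions`` samples ×
    populations with rows summing to 1.
    """
    missing = set(proportions.columns) ^ set(reference.columns)
    if missing:
        raise ValueError(f"population labels disagree: {sorted(missing)}")
    props = proportions[reference.columns]
    arr = props.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("proportions must be non-negative")
    if np.abs(arr.sum(axis=1) - 1).max() > 1e-8:
        raise ValueError("proportion vectors must sum to 1 (within 1e-8)")
    rng = np.random.default_rng(seed)
    mixed = reference.to_numpy(dtype=float) @ arr.T
    if noise_sd > 0:
        mixed = mixed + rng.normal(0.0, noise_sd, size=mixed.shape)
    mixed = np.maximum(mixed, 0.0)
    values = pd.DataFrame(mixed, index=reference.index, columns=props.index)
    return ExpressionMatrix(values, layer="TPM")


_GROWTH_DAYS = (0, 3, 7, 10, 14, 17, 21, 24, 28)


def simulate_growth_curves(arm_spec: Sequence[str], seed: int = 0, cage_size: int = 5) -> list[GrowthCurve]:
    """Tumour-area curves with intended outcomes, cages filled round-robin.

    ``arm_spec`` assigns each mouse one of ``complete_regression``,
    ``progression`` or ``partial``. Curves start at ~9 mm² (the size at
    surgery) and are measured through day 28.
    """
    rng = np.random.default_rng(seed)
    days = np.asarray(_GROWTH_DAYS, dtype=float)
    curves = []
    for i, intent in enumerate(arm_spec):
        if intent == "progression":
            rate = rng.uniform(0.14, 0.20)
            areas = np.minimum(9.0 * np.exp(rate * days), 150.0)
        elif intent == "complete_regression":
            rate = rng.uniform(1.2, 2.0)
            areas = np.maximum(9.0 - rate * days, 0.0)
        elif intent == "partial":
            nadir = rng.uniform(2.0, 5.0)
            final = rng.uniform(25.0, 60.0)
            areas = np.interp(days, [0.0, 10.0, 28.0], [9.0, nadir, final])
        else:
            raise ValueError(f"unknown intended outcome {intent!r}")
        curves.append(
            GrowthCurve(
                mouse_id=f"mouse{i + 1:03d}",
                cage_id=f"cage{i // cage_size + 1:02d}",
                days=days,
                areas_mm2=areas,
            )
        )
    return curves


def _survival_arrays(spec: PowerSpec, rng: np.random.Generator):
    """Raw draws behind :func:`simulate_survival` (shared with the power loop)."""
    lam_c = np.log(2.0) / spec.control_median_days
    lam_e = lam_c / spec.hazard_ratio
    t_c = rng.exponential(1.0 / lam_c, size=spec.n_per_group)
    t_e = rng.exponential(1.0 / lam_e, size=spec.n_per_group)
    e_c = np.ones(spec.n_per_group, dtype=bool)
    e_e = np.ones(spec.n_per_group, dtype=bool)
    if spec.admin_censor_day is not None:
        e_c = t_c <= spec.admin_censor_day
        e_e = t_e <= spec.admin_censor_day
        t_c = np.minimum(t_c, spec.admin_censor_day)
        t_e = np.minimum(t_e, spec.admin_censor_day)
    return t_c, e_c, t_e, e_e


def simulate_survival(spec: PowerSpec, seed: int | None = None, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Exponential survival records (group, time, event) under ``spec``.

    Control times have median ``spec.control_median_days``; the
    experimental hazard is the control hazard divided by the hazard ratio,
    so experimental animals survive longer when HR > 1. All events are
    observed unless ``admin_censor_day`` is set.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
    t_c, e_c, t_e, e_e = _survival_arrays(spec, rng)
    return pd.DataFrame(
        {
            "group": ["control"] * spec.n_per_group + ["experimental"] * spec.n_per_group,
            "time": np.concatenate([t_c, t_e]),
            "event": np.concatenate([e_c, e_e]).astype(int),
        }
    )


def simulate_velocity_embedding(
    n_cells_per_group: Mapping[str, int],
    group_scale_factors: Mapping[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Isotropic Gaussian 2-D embedding-velocity vectors per labelled group.

    A group with scale σ has E‖v‖² = 2σ². Scale 0 is allowed and yields
    exactly zero vectors.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in n_cells_per_group.items():
        scale = float(group_scale_factors[group])
        if scale < 0:
            raise ValueError(f"scale for {group!r} must be >= 0")
        v = rng.normal(0.0, 1.0, size=(n, 2)) * scale
        for i in range(n):
            rows.append({"cell_id": f"{group}_c{i + 1:05d}", "vx": v[i, 0], "vy": v[i, 1], "group": group})
    return pd.DataFrame(rows).set_index("cell_id")
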