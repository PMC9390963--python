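"""Tumour response classification, cage dichotomy filtering and survival design.

The in-vivo arm of the analysis labels each mouse by the fate of its
remaining tumour after checkpoint blockade: *responder* (complete
regression sustained through four weeks), *non-responder* (tumour reaches
100 mm² within four weeks, like saline controls) or *intermediate*
(anything in between; excluded from analysis). Cages are kept only when
they show a dichotomous response, i.e. at least one responder and one
non-responder after intermediates are dropped.

The survival design assumes exponential survival with a control median of
35 days and asks for the power of a two-sided log-rank test at a true
control-vs-experimental hazard ratio of 5 with 10 mice per group. The
log-rank statistic is computed directly (vectorised over distinct event
times) so the Monte-Carlo power loop stays fast; its analytic companion is
the Schoenfeld approximation Φ(√(d/4)·|ln HR| − z₁₋α/₂) with d total
events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "GrowthCurve",
    "ResponseCall",
    "PowerSpec",
    "classify_response",
    "dichotomy_filter",
    "logrank_test",
    "simulate_power",
    "schoenfeld_power",
]


@dataclass
class GrowthCurve:
    """Per-mouse tumour area time series (days since start of treatment)."""

    mouse_id: str
    cage_id: str
    days: np.ndarray
    areas_mm2: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.areas_mm2 = np.asarray(self.areas_mm2, dtype=float)
        if self.days.size != self.areas_mm2.size:
            raise ValueError("days and areas differ in length")
        if self.days.size < 2:
            raise ValueError(f"curve for {self.mouse_id} needs >= 2 measurements")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError(f"days must be strictly increasing for {self.mouse_id}")
        if np.any(self.areas_mm2 < 0):
            raise ValueError(f"negative tumour area for {self.mouse_id}")


@dataclass(frozen=True)
class ResponseCall:
    mouse_id: str
    call: str  # responder | non_responder | intermediate

    def __post_init__(self):
        if self.call not in ("responder", "non_responder", "intermediate"):
            raise ValueError(f"unknown call {self.call!r}")


@dataclass
class PowerSpec:
    """Design parameters for the log-rank power simulation.

    ``hazard_ratio`` is control vs experimental: HR > 1 means experimental
    animals survive longer (hazard divided by HR).
    """

    hazard_ratio: float = 5.0
    n_per_group: int = 10
    alpha: float = 0.05
    control_median_days: float = 35.0
    admin_censor_day: float | None = None
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.control_median_days <= 0:
            raise ValueError("control median must be positive")
        if self.n_per_group < 2:
            raise ValueError("need >= 2 subjects per group")


def classify_response(
    curve: GrowthCurve,
    progression_area: float = 100.0,
    window_days: float = 28.0,
    regression_area: float = 0.0,
) -> ResponseCall:
    """Deterministic response call from a growth curve.

    Non-responder if the tumour reaches ``progression_area`` (≥, inclusive)
    at any measurement within ``window_days``; otherwise responder if the
    area drops to ``regression_area`` or below and stays there through the
    last in-window measurement; otherwise intermediate.
    """
    in_window = curve.days <= window_days
    if not in_window.any():
        raise ValueError(f"no measurements within {window_days} days for {curve.mouse_id}")
    areas = curve.areas_mm2[in_window]
    if np.any(areas >= progression_area):
        return ResponseCall(curve.mouse_id, "non_responder")
    regressed = np.flatnonzero(areas <= regression_area)
    if regressed.size and np.all(areas[regressed[0]:] <= regression_area):
        return ResponseCall(curve.mouse_id, "responder")
    return ResponseCall(curve.mouse_id, "intermediate")


def dichotomy_filter(
    calls: Iterable[ResponseCall], cage_of_mouse: Mapping[str, str]
) -> list[str]:
    """Cage ids showing a dichotomous response.

    A cage is kept iff, after excluding intermediate responders, it houses
    at least one responder *and* at least one non-responder.
    """
    per_cage: dict[str, set[str]] = {}
    for call in calls:
        try:
            cage = cage_of_mouse[call.mouse_id]
        except KeyError:
            raise ValueError(f"mouse {call.mouse_id} has no cage assignment") from None
        per_cage.setdefault(cage, set())
        if call.call != "intermediate":
            per_cage[cage].add(call.call)
    return sorted(c for c, kinds in per_cage.items() if kinds == {"responder", "non_responder"})


def logrank_test(times_a, events_a, times_b, events_b) -> dict:
    """Two-group log-rank (Mantel–Cox) test.

    At each distinct event time the observed minus expected events in group
    A are accumulated with the hypergeometric variance;
    ``chi2 = (ΣO−E)² / ΣV`` is referred to a chi-square with 1 df.

    Returns a dict with ``chi2``, ``p``, ``observed_a`` and ``expected_a``.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size != ea.size or tb.size != eb.size:
        raise ValueError("times and events differ in length")
    if ta.size < 2 or tb.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (ea.any() or eb.any()):
        warnings.warn("no events in either group; log-rank undefined, p = 1", stacklevel=2)
        return {"chi2": 0.0, "p": 1.0, "observed_a": 0.0, "expected_a": 0.0}

    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])

    event_times = np.unique(times[events])
    # risk-set sizes just before each event time
    n_tot = (times[None, :] >= event_times[:, None]).sum(axis=1).astype(float)
    n_a = ((times[None, :] >= event_times[:, None]) & group_a[None, :]).sum(axis=1).astype(float)
    at_t = times[None, :] == event_times[:, None]
    d_tot = (at_t & events[None, :]).sum(axis=1).astype(float)
    d_a = (at_t & events[None, :] & group_a[None, :]).sum(axis=1).astype(float)

    expected = d_tot * n_a / n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        var = d_tot * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    var = np.where(n_tot > 1, var, 0.0)

    o_minus_e = float((d_a - expected).sum())
    v = float(var.sum())
    if v == 0:
        warnings.warn("zero log-rank variance; p = 1", stacklevel=2)
        return {"chi2": 0.0, "p": 1.0, "observed_a": float(d_a.sum()), "expected_a": float(expected.sum())}
    chi2 = o_minus_e**2 / v
    return {
        "chi2": chi2,
        "p": float(stats.chi2.sf(chi2, df=1)),
        "observed_a": float(d_a.sum()),
        "expected_a": float(expected.sum()),
    }


def schoenfeld_power(spec: PowerSpec, total_events: int) -> float:
    """Analytic log-rank power: Φ(√(d/4)·|ln HR| − z₁₋α/₂)."""
    if total_events < 1:
        raise ValueError("total_events must be >= 1")
    z = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(np.sqrt(total_events / 4.0) * abs(np.log(spec.hazard_ratio)) - z))


def simulate_power(spec: PowerSpec) -> dict:
    """Monte-Carlo power of the two-sided log-rank test under ``spec``.

    Each replicate draws exponential survival for both groups (control
    hazard ln2/median, experimental hazard divided by the hazard ratio),
    applies :func:`logrank_test`, and counts rejections at ``spec.alpha``.
    Returns ``power_estimate``, its Monte-Carlo standard error and ``reps``.
    """
    # Local import: synthetic_data owns the survival draw, this module the
    # test; importing lazily keeps the modules acyclic.
    from onoffgrn.synthetic import _survival_arrays

    if spec.reps < 1000:
        raise ValueError("reps must be >= 1000 for a stable estimate")
    rng = np.random.default_rng(spec.seed)
    rejections = 0
    for _ in range(spec.reps):
        t_c, e_c, t_e, e_e = _survival_arrays(spec, rng)
        res = logrank_test(t_c, e_c, t_e, e_e)
        if res["p"] < spec.alpha:
            rejections += 1
    p_hat = rejections / spec.reps
    return {
        "power_estimate": p_hat,
        "mc_se": float(np.sqrt(p_hat * (1 - p_hat) / spec.reps)),
        "reps": spec.reps,
    }
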