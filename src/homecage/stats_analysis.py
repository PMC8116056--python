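"""Performance metrics, resampling inference and ephys modulation metrics.

* ``performance`` — percent correct over scored (non-ignore) trials.
* ``nested_bootstrap_effect`` — significance of a photostimulation-induced
  performance change via a hierarchical bootstrap: mice are resampled with
  replacement, then sessions within each drawn mouse, then trials within
  each drawn session; the within-mouse performance change (photostim minus
  control) is averaged across the drawn mice.  The one-tailed p-value is the
  fraction of resamples whose effect has the sign opposite to the observed
  one.  A day (dark + light cycle) of home-cage data is one session.
* ``chisq_proportions`` — Pearson chi-square on a 2x2 table (1 df, no
  continuity correction).
* ``ifi_by_outcome`` — inter-fixation intervals partitioned by the outcome
  of the last scored trial in the preceding fixation.
* ``classify_unit_and_modulation`` — putative cell class from spike width
  (trough-to-peak < 0.55 ms = fast-spiking) and the per-intensity relative
  firing rate (stimulation rate / 500 ms pre-stimulus baseline rate) with a
  paired two-tailed t-test across sweeps.

Trial resampling is implemented as multinomial draws over each session's
(condition x outcome) category counts — statistically identical to drawing
trial indices with replacement, and vectorizable across resamples.  Every
drawn copy of a mouse or session receives an independent lower-level
resample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .headfix_protocol import FixationEvent
from .trial_engine import Outcome, TrialRecord

__all__ = [
    "BootstrapResult",
    "UnitModulation",
    "performance",
    "nested_bootstrap_effect",
    "chisq_proportions",
    "ifi_by_outcome",
    "classify_unit_and_modulation",
    "trials_to_frame",
]

FS_SPIKE_WIDTH_MS = 0.55
BASELINE_WINDOW_S = 0.5
STIM_WINDOW_S = 1.3

_OUTCOMES = ("correct", "error", "ignore")


@dataclass(frozen=True)
class BootstrapResult:
    """Observed effect (percentage points) and its bootstrap distribution."""

    observed_effect: float
    n_resamples: int
    p_one_tailed: float
    resample_mean: float
    resample_sd: float
    quantiles: dict  # {2.5, 50, 97.5} -> value


@dataclass
class UnitModulation:
    """Photostimulation modulation metrics for one recorded unit."""

    unit_id: str
    spike_width_ms: float
    cell_class: str  # 'FS' | 'pyramidal' | 'unclassified'
    baseline_rate_hz: float
    stim_rate_hz: dict = field(default_factory=dict)  # intensity -> Hz
    relative_firing_rate: dict = field(default_factory=dict)  # intensity -> ratio
    modulation_p: dict = field(default_factory=dict)  # intensity -> two-tailed p
    baseline_defined: bool = True


def performance(trials: Iterable, by_type: bool = False):
    """Percent correct over scored trials (ignores excluded).

    Accepts TrialRecord sequences or any iterable of objects/strings with an
    outcome.  With ``by_type=True`` returns a dict keyed by trial type.
    """
    trials = list(trials)
    if by_type:
        out = {}
        for tt in sorted({t.trial_type for t in trials}, key=str):
            out[tt] = performance([t for t in trials if t.trial_type is tt])
        return out
    n_corr = n_err = 0
    for t in trials:
        o = t.outcome if hasattr(t, "outcome") else t
        o = o.value if isinstance(o, Outcome) else str(o)
        if o == "correct":
            n_corr += 1
        elif o == "error":
            n_err += 1
    if n_corr + n_err == 0:
        raise ValueError("no scored trials")
    return 100.0 * n_corr / (n_corr + n_err)


def trials_to_frame(trials: Sequence[TrialRecord], mouse: str, session) -> pd.DataFrame:
    """Flatten trial records into the grouped-trials table used for inference."""
    return pd.DataFrame(
        {
            "mouse": mouse,
            "session": session,
            "condition": ["photostim" if t.photostim is not None else "control"
                          for t in trials],
            "outcome": [t.outcome.value for t in trials],
        }
    )


def _session_counts(df: pd.DataFrame, conditions: tuple[str, str]) -> dict:
    """Per-mouse list of per-session category-count vectors.

    Categories: (condition0, condition1) x (correct, error, ignore) -> 6.
    """
    cats = [(c, o) for c in conditions for o in _OUTCOMES]
    out: dict[str, list[np.ndarray]] = {}
    for (mouse, _session), g in df.groupby(["mouse", "session"], sort=True):
        counts = np.zeros(len(cats))
        vc = g.groupby(["condition", "outcome"]).size()
        for k, (c, o) in enumerate(cats):
            counts[k] = vc.get((c, o), 0)
        out.setdefault(mouse, []).append(counts)
    return out


def _perf_delta(counts: np.ndarray) -> float:
    """Performance change cond1 - cond0 (percentage points) from a 6-vector.

    Layout: [c0_corr, c0_err, c0_ign, c1_corr, c1_err, c1_ign].
    NaN when either condition has no scored trials.
    """
    n0 = counts[..., 0] + counts[..., 1]
    n1 = counts[..., 3] + counts[..., 4]
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.where(n0 > 0, 100.0 * counts[..., 0] / np.maximum(n0, 1), np.nan)
        p1 = np.where(n1 > 0, 100.0 * counts[..., 3] / np.maximum(n1, 1), np.nan)
    return p1 - p0


def nested_bootstrap_effect(
    data: pd.DataFrame,
    conditions: tuple[str, str] = ("control", "photostim"),
    n_resamples: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> BootstrapResult:
    """Hierarchical mouse/session/trial bootstrap of a performance change.

    ``data`` has columns mouse, session, condition, outcome.  The observed
    effect is each mouse's performance under ``conditions[1]`` minus
    ``conditions[0]`` (sessions pooled), averaged unweighted across mice.
    Each resample redraws mice, then sessions within each drawn mouse, then
    trials within each drawn session.  Mice lacking one condition are
    dropped with a warning.  With a single mouse and session the procedure
    reduces to a plain trial bootstrap.
    """
    if rng is None:
        rng = np.random.default_rng()
    required = {"mouse", "session", "condition", "outcome"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    present = set(data["condition"].unique())
    missing = set(conditions) - present
    if missing:
        raise ValueError(f"conditions absent from data: {sorted(missing)}")

    by_mouse = _session_counts(data, conditions)
    mice = []
    for mouse, sess in by_mouse.items():
        pooled = np.sum(sess, axis=0)
        if (pooled[0] + pooled[1]) == 0 or (pooled[3] + pooled[4]) == 0:
            warnings.warn(f"mouse {mouse!r} lacks scored trials in one condition; dropped")
            continue
        mice.append(mouse)
    if not mice:
        raise ValueError("no mouse has scored trials in both conditions")

    observed = float(np.mean([
        _perf_delta(np.sum(by_mouse[m], axis=0)) for m in mice
    ]))

    M = len(mice)
    R = n_resamples
    # delta[mi, slot, r]: independent mouse-level replicate per draw slot
    delta = np.empty((M, M, R))
    for mi, m in enumerate(mice):
        sessions = by_mouse[m]
        S = len(sessions)
        n_per = [int(c.sum()) for c in sessions]
        p_per = [c / max(c.sum(), 1) for c in sessions]
        for slot in range(M):
            picks = rng.integers(0, S, size=(R, S))
            agg = np.zeros((R, 6))
            for s in range(S):
                occ_rows = np.nonzero(picks == s)[0]
                if occ_rows.size == 0:
                    continue
                draws = rng.multinomial(n_per[s], p_per[s], size=occ_rows.size)
                np.add.at(agg, occ_rows, draws)
            delta[mi, slot] = _perf_delta(agg)

    mouse_draw = rng.integers(0, M, size=(R, M))
    d = delta[mouse_draw, np.arange(M)[None, :], np.arange(R)[:, None]]  # (R, M)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        effects = np.nanmean(d, axis=1)
    effects = effects[np.isfinite(effects)]
    if effects.size == 0:
        raise ValueError("all bootstrap resamples degenerate")

    if observed > 0:
        p = float(np.mean(effects < 0))
    elif observed < 0:
        p = float(np.mean(effects > 0))
    else:
        p = 0.5
    qs = np.percentile(effects, [2.5, 50, 97.5])
    return BootstrapResult(
        observed_effect=observed,
        n_resamples=n_resamples,
        p_one_tailed=p,
        resample_mean=float(np.mean(effects)),
        resample_sd=float(np.std(effects)),
        quantiles={2.5: float(qs[0]), 50: float(qs[1]), 97.5: float(qs[2])},
    )


def chisq_proportions(table) -> float:
    """Pearson chi-square p-value for a 2x2 count table (1 df, no correction)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square undefined")
    _, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(p)


def ifi_by_outcome(
    fixations: Sequence[FixationEvent],
    trials: Sequence[TrialRecord],
) -> dict[str, tuple[float, int]]:
    """Mean inter-fixation interval by the preceding fixation's last outcome.

    The IFI after fixation *i* is the interval from its release to the start
    of fixation *i+1*.  It is classified by the outcome of the last scored
    trial within fixation *i*; fixations with no scored trial leave their
    following interval unclassified.  Returns outcome -> (mean_ifi, count).
    """
    by_index = {t.trial_index: t for t in trials}
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    fixations = sorted(fixations, key=lambda f: f.start_time)
    for prev, nxt in zip(fixations[:-1], fixations[1:]):
        if prev.first_trial_index is None or prev.n_trials_completed == 0:
            continue
        last_outcome = None
        for k in range(prev.first_trial_index + prev.n_trials_completed - 1,
                       prev.first_trial_index - 1, -1):
            t = by_index.get(k)
            if t is not None and t.outcome is not Outcome.IGNORE:
                last_outcome = t.outcome.value
                break
        if last_outcome is None:
            continue
        ifi = nxt.start_time - prev.end_time
        sums[last_outcome] = sums.get(last_outcome, 0.0) + ifi
        counts[last_outcome] = counts.get(last_outcome, 0) + 1
    return {k: (sums[k] / counts[k], counts[k]) for k in sums}


def classify_unit_and_modulation(
    sweeps: pd.DataFrame,
    baseline_window_s: float = BASELINE_WINDOW_S,
    stim_window_s: float = STIM_WINDOW_S,
    classify_by_width: bool = True,
) -> UnitModulation:
    """Cell-class and photostimulation modulation metrics for one unit.

    ``sweeps`` columns: unit_id, spike_width_ms, intensity_mw_mm2, sweep,
    baseline_count, stim_count.  Spike width < 0.55 ms (strict) classifies a
    unit as putative fast-spiking; wider units are putative pyramidal
    (``classify_by_width=False`` leaves units unclassified, as in
    subcortical structures).  The unit's baseline rate pools all sweeps; per
    intensity, the relative firing rate is the mean stimulation rate divided
    by that baseline, and significance is a paired two-tailed t-test of
    per-sweep stimulation vs baseline rates.
    """
    unit_ids = sweeps["unit_id"].unique()
    if len(unit_ids) != 1:
        raise ValueError("classify_unit_and_modulation expects one unit at a time")
    width = float(sweeps["spike_width_ms"].iloc[0])
    if classify_by_width:
        cell_class = "FS" if width < FS_SPIKE_WIDTH_MS else "pyramidal"
    else:
        cell_class = "unclassified"

    base_rates_all = sweeps["baseline_count"].to_numpy(float) / baseline_window_s
    baseline = float(np.mean(base_rates_all))
    unit = UnitModulation(
        unit_id=str(unit_ids[0]),
        spike_width_ms=width,
        cell_class=cell_class,
        baseline_rate_hz=baseline,
        baseline_defined=baseline > 0,
    )
    for intensity, g in sweeps.groupby("intensity_mw_mm2", sort=True):
        stim_rates = g["stim_count"].to_numpy(float) / stim_window_s
        base_rates = g["baseline_count"].to_numpy(float) / baseline_window_s
        unit.stim_rate_hz[float(intensity)] = float(np.mean(stim_rates))
        if unit.baseline_defined:
            unit.relative_firing_rate[float(intensity)] = float(
                np.mean(stim_rates) / baseline
            )
        if len(g) >= 2 and (np.std(stim_rates - base_rates) > 0):
            _, p = sps.ttest_rel(stim_rates, base_rates)
            unit.modulation_p[float(intensity)] = float(p)
        else:
            unit.modulation_p[float(intensity)] = float("nan")
    return unit
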