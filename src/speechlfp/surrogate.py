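"""Shuffled-baseline surrogate null and pixel-wise significance masks.

The null distribution for each frequency (and contact) is built by
repeatedly drawing, independently for every trial, one time sample
uniformly at random from the baseline period (-1000, -500] ms of the
dB-normalized power, and averaging the draws across trials. This is the
baseline bootstrap commonly used for event-related spectral perturbations:
each surrogate value is one realization of "trial-mean baseline power", so
an observed pixel that escapes the null reflects a genuine event-locked
departure from baseline. Observed maps are compared two-tailed against the
null with the add-one permutation convention (p is never exactly 0); with
the default 2,241 shuffles the smallest attainable two-tailed p is
2/2,242 ~ 8.9e-4, just below the 0.001 threshold.

No multiple-comparison correction is applied; masks are evaluated only on
the -500..+1000 ms window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import EVAL_WINDOW_MS, SHUFFLE_BASELINE_MS, TFMap, TrialPowerTensor
from .timefreq import grand_average, trial_average

DEFAULT_N_SHUFFLES = 2241
DEFAULT_ALPHA = 0.001

#: below this shuffle count a two-tailed p < 0.001 is at the resolution limit
SHUFFLE_RESOLUTION_WARNING = 2000
SHUFFLE_MINIMUM = 200


@dataclass
class SurrogateNull:
    """Empirical null: values is (n_shuffles, n_channels, n_freqs)."""

    values: np.ndarray
    freqs_hz: np.ndarray
    channels: list[str]
    baseline_window_ms: tuple
    seed: int | None = None

    @property
    def n_shuffles(self) -> int:
        return self.values.shape[0]


@dataclass
class ThresholdedTFMap:
    """A TFMap with its two-tailed surrogate p-values and significance mask."""

    map: TFMap
    p: np.ndarray
    mask: np.ndarray
    alpha: float = DEFAULT_ALPHA
    comparison: str = "within-condition"
    valid: np.ndarray | None = None  # pixels the test was evaluated on

    def masked_data(self) -> np.ndarray:
        """Map with non-significant pixels set to 0 dB (display convention)."""
        return np.where(self.mask, self.map.data, 0.0)


def _check_shuffles(n_shuffles: int) -> None:
    if n_shuffles < SHUFFLE_MINIMUM:
        raise ValueError(f"n_shuffles must be >= {SHUFFLE_MINIMUM}")
    if n_shuffles < SHUFFLE_RESOLUTION_WARNING:
        warnings.warn(
            f"n_shuffles={n_shuffles} cannot resolve two-tailed p < 0.001 "
            f"(smallest attainable p is {2.0 / (n_shuffles + 1):.2e}); "
            "use >= 2000 shuffles for the default threshold", UserWarning,
            stacklevel=3)


def build_null(tensor: TrialPowerTensor, baseline_window_ms=SHUFFLE_BASELINE_MS,
               n_shuffles: int = DEFAULT_N_SHUFFLES, seed=None,
               chunk: int = 256) -> SurrogateNull:
    """Surrogate null from per-trial random baseline sampling.

    For each of n_shuffles iterations, one baseline time point is drawn per
    trial (uniformly from (-1000, -500] ms) and the drawn dB values are
    averaged across trials, yielding one surrogate statistic per contact and
    frequency.
    """
    if tensor.kind != "db":
        raise ValueError("build_null expects a dB-normalized tensor")
    if tensor.n_trials < 2:
        raise ValueError("need >= 2 trials to build a surrogate null")
    _check_shuffles(n_shuffles)
    t = tensor.times_ms
    lo, hi = baseline_window_ms
    keep = (t > lo) & (t <= hi)  # half-open on the left, matching (-1000, -500]
    if not keep.any():
        raise ValueError("baseline window lies outside the epoch")
    base = np.ascontiguousarray(tensor.power[..., keep])  # (T, C, F, B)
    n_trials, _, _, n_base = base.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trial_ix = np.arange(n_trials)[None, :]
    out = np.empty((n_shuffles, base.shape[1], base.shape[2]))
    for s0 in range(0, n_shuffles, chunk):
        s1 = min(s0 + chunk, n_shuffles)
        idx = rng.integers(0, n_base, size=(s1 - s0, n_trials))
        # advanced indices on axes 0 and 3 -> (chunk, T, C, F)
        out[s0:s1] = base[trial_ix, :, :, idx].mean(axis=1)
    return SurrogateNull(out, tensor.freqs_hz.copy(), list(tensor.channels),
                         tuple(baseline_window_ms))


def pool_nulls(nulls: list[SurrogateNull]) -> SurrogateNull:
    """Group-level null: elementwise mean of participant-level draws.

    Mirrors how the observed grand average is formed from participant maps;
    shuffle i of the pooled null averages shuffle i of every participant.
    """
    if not nulls:
        raise ValueError("no nulls to pool")
    shapes = {n.values.shape for n in nulls}
    if len(shapes) != 1:
        raise ValueError("participant nulls must share n_shuffles and grid")
    return SurrogateNull(np.mean([n.values for n in nulls], axis=0),
                         nulls[0].freqs_hz, list(nulls[0].channels),
                         nulls[0].baseline_window_ms)


def pixel_p(observed: TFMap, null: SurrogateNull) -> np.ndarray:
    """Two-tailed empirical p per pixel, add-one convention, capped at 1."""
    if observed.data.shape[1] != null.values.shape[2] or \
            observed.data.shape[0] != null.values.shape[1]:
        raise ValueError("observed map and null must share contact/frequency axes")
    n = null.n_shuffles
    p = np.empty_like(observed.data)
    for c in range(observed.data.shape[0]):
        for f in range(observed.data.shape[1]):
            surr = np.sort(null.values[:, c, f])
            obs = observed.data[c, f]
            n_le = np.searchsorted(surr, obs, side="right")
            n_ge = n - np.searchsorted(surr, obs, side="left")
            p[c, f] = 2.0 * np.minimum((1 + n_ge) / (n + 1.0), (1 + n_le) / (n + 1.0))
    return np.minimum(p, 1.0)


def threshold(observed: TFMap, null: SurrogateNull, alpha: float = DEFAULT_ALPHA,
              eval_window_ms=EVAL_WINDOW_MS,
              comparison: str = "within-condition") -> ThresholdedTFMap:
    """Pixel-wise two-tailed mask at alpha over the valid evaluation pixels.

    Valid pixels lie inside the evaluation window and outside the epoch-edge
    flags (where the wavelet kernel overlaps the zero padding and dB power
    is biased low); flagged pixels are never declared significant.
    """
    p = pixel_p(observed, null)
    in_window = ((observed.times_ms >= eval_window_ms[0])
                 & (observed.times_ms <= eval_window_ms[1]))
    valid = np.broadcast_to(in_window[None, None, :], observed.data.shape).copy()
    if observed.edge_mask is not None:
        valid &= ~observed.edge_mask[None, :, :]
    mask = (p < alpha) & valid
    return ThresholdedTFMap(observed, p, mask, alpha, comparison, valid=valid)


def within_condition(tensors: list[TrialPowerTensor], task: str,
                     n_shuffles: int = DEFAULT_N_SHUFFLES, seed=None,
                     alpha: float = DEFAULT_ALPHA) -> ThresholdedTFMap:
    """Group-level within-condition test across participants.

    Observed statistic: grand average of participant trial-mean maps for the
    task. Null: participant-level surrogate draws averaged across
    participants (pool_nulls), so null and observed aggregate identically.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(tensors))
    maps, nulls = [], []
    for tensor, child in zip(tensors, children):
        sel = tensor.select_task(task)
        maps.append(trial_average(sel))
        nulls.append(build_null(sel, n_shuffles=n_shuffles,
                                seed=np.random.default_rng(child)))
    obs = grand_average(maps)
    obs.condition = task
    return threshold(obs, pool_nulls(nulls), alpha, comparison="within-condition")


def contrast(tensors_a: list[TrialPowerTensor], tensors_b: list[TrialPowerTensor],
             n_shuffles: int = DEFAULT_N_SHUFFLES, seed=None,
             alpha: float = DEFAULT_ALPHA, label: str = "A-B") -> ThresholdedTFMap:
    """Between-condition comparison on unthresholded difference maps.

    For each participant the condition maps are subtracted first (A - B);
    the observed statistic is the participant-mean difference map. The null
    applies the same shuffle scheme to each condition's baseline
    independently and differences the draws, then pools across participants.
    """
    if len(tensors_a) != len(tensors_b):
        raise ValueError("conditions must cover the same participants")
    for ta, tb in zip(tensors_a, tensors_b):
        if ta.participant_id != tb.participant_id:
            raise ValueError("participant order must match between conditions")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(tensors_a))
    maps, nulls = [], []
    for i, (ta, tb) in enumerate(zip(tensors_a, tensors_b)):
        map_a, map_b = trial_average(ta), trial_average(tb)
        d = TFMap(map_a.data - map_b.data, ta.freqs_hz, ta.times_ms,
                  list(ta.channels), level="participant", condition=label,
                  participant_id=ta.participant_id, hemisphere=ta.hemisphere,
                  edge_mask=map_a.edge_mask)
        maps.append(d)
        na = build_null(ta, n_shuffles=n_shuffles,
                        seed=np.random.default_rng(children[2 * i]))
        nb = build_null(tb, n_shuffles=n_shuffles,
                        seed=np.random.default_rng(children[2 * i + 1]))
        nulls.append(SurrogateNull(na.values - nb.values, na.freqs_hz,
                                   list(na.channels), na.baseline_window_ms))
    obs = grand_average(maps)
    obs.condition = label
    return threshold(obs, pool_nulls(nulls), alpha, comparison="between-condition")
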