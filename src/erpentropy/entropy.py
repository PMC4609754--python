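"""Signal-entropy estimators and the event-related sliding-window schedule.

This module implements the two entropy measures used throughout the package:

* :func:`shannon_entropy` — the classical discrete entropy
  ``H = -sum_i p_i ln p_i`` of a probability distribution, in nats.
* :func:`sample_entropy` — sample entropy (sampEn) of a finite time series,
  the negative log of the conditional probability that runs of ``m``
  consecutive samples that are similar (within a tolerance ``r``) remain
  similar when extended to ``m + 1`` samples.  Following Richman & Moorman's
  convention, ``N - m`` templates are formed for both lengths, self-matches
  are excluded, and similarity is judged with the Chebyshev (max-norm)
  distance by default.  The tolerance is ``r_multiplier`` times the standard
  deviation of the frame being analyzed, so sampEn is amplitude-scale free.

For event-related analysis, a rectangular window (default 500 ms) slides in
fixed steps (default 100 ms) across the post-stimulus epoch, and sampEn is
computed within each window with the tolerance recomputed from that window's
own standard deviation (:func:`sliding_window_entropy`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SampEnParams",
    "SampEnResult",
    "WindowSchedule",
    "shannon_entropy",
    "sample_entropy",
    "sample_entropy_batch",
    "sliding_window_entropy",
]


@dataclass(frozen=True)
class SampEnParams:
    """Configuration of the sample-entropy estimator.

    Parameters
    ----------
    m : int
        Template (block) length in samples. Must be >= 1.
    r_multiplier : float
        Similarity tolerance expressed as a multiple of the standard
        deviation of the analyzed frame. Must be > 0.
    distance : {"chebyshev", "euclidean"}
        Distance measure between templates. Chebyshev (max-norm) is the
        Richman–Moorman convention and the default.
    """

    m: int = 2
    r_multiplier: float = 0.25
    distance: str = "chebyshev"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"template length m must be >= 1, got {self.m}")
        if not self.r_multiplier > 0:
            raise ValueError(
                f"r_multiplier must be > 0, got {self.r_multiplier}"
            )
        if self.distance not in ("chebyshev", "euclidean"):
            raise ValueError(
                "distance must be 'chebyshev' or 'euclidean', "
                f"got {self.distance!r}"
            )


@dataclass
class SampEnResult:
    """Outcome of one sample-entropy evaluation.

    ``value`` is ``-ln(n_template_matches_m1 / n_template_matches_m)`` when
    defined.  ``degenerate`` flags the two conventions for ill-posed frames:
    a zero-variance frame yields ``value = 0`` (all templates identical), and
    a zero match count at either length yields ``value = nan`` (undefined,
    propagated downstream as missing).  Match counts are over ordered pairs
    ``i != j`` of the ``N - m`` templates.
    """

    value: float
    n_template_matches_m: int
    n_template_matches_m1: int
    frame_sd: float
    degenerate: bool = False


@dataclass(frozen=True)
class WindowSchedule:
    """Sliding rectangular-window schedule over a stimulus-locked epoch.

    Defaults follow the event-related protocol: a 500 ms window moved in
    100 ms steps, with centers from +250 ms to +1250 ms post-stimulus, so the
    last window spans the +1000..+1500 ms period.  All ms-to-sample
    conversions use ``round(ms * fs / 1000)``; the window is the half-open
    sample interval ``[start, start + window_samples)`` with
    ``start = round((center_ms - window_ms / 2) * fs / 1000)``, which at
    250 Hz yields exactly 125 samples per 500 ms window.
    """

    window_ms: float = 500.0
    step_ms: float = 100.0
    first_center_ms: float = 250.0
    last_center_ms: float = 1250.0
    sampling_rate_hz: float = 250.0

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window_ms and step_ms must be positive")
        if self.last_center_ms < self.first_center_ms:
            raise ValueError("last_center_ms must be >= first_center_ms")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def window_samples(self) -> int:
        """Window length in samples: round(window_ms * fs / 1000)."""
        return int(round(self.window_ms * self.sampling_rate_hz / 1000.0))

    @property
    def centers_ms(self) -> np.ndarray:
        """Arithmetic sequence of window centers, in ms post-stimulus."""
        n = int(round((self.last_center_ms - self.first_center_ms) / self.step_ms)) + 1
        return self.first_center_ms + self.step_ms * np.arange(n)

    def start_index(self, center_ms: float, t0_sample: int = 0) -> int:
        """First sample index of the window centered at ``center_ms``."""
        fs = self.sampling_rate_hz
        return t0_sample + int(round((center_ms - self.window_ms / 2.0) * fs / 1000.0))


def shannon_entropy(probabilities) -> float:
    """Shannon entropy ``-sum p ln p`` (nats) of a discrete distribution.

    ``0 * ln 0`` is taken as 0.  Probabilities must be non-negative and sum
    to 1 within 1e-9.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("probabilities must be a non-empty 1-D vector")
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1 (got {total!r})")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _template_distance_matrices(x: np.ndarray, m: int, distance: str):
    """Pairwise template distances at lengths m and m+1.

    Both lengths use the first ``N - m`` templates (Richman–Moorman), so a
    match at m+1 implies a match at m and sampEn is non-negative by
    construction.  Returns (D_m, D_m1), each ``(N-m, N-m)``.
    """
    n_templates = x.size - m
    d0 = np.abs(x[:, None] - x[None, :])
    if distance == "euclidean":
        d0 = d0**2
    acc_m = d0[:n_templates, :n_templates].copy()
    for k in range(1, m):
        block = d0[k : k + n_templates, k : k + n_templates]
        if distance == "chebyshev":
            np.maximum(acc_m, block, out=acc_m)
        else:
            acc_m += block
    block = d0[m : m + n_templates, m : m + n_templates]
    if distance == "chebyshev":
        acc_m1 = np.maximum(acc_m, block)
    else:
        acc_m1 = acc_m + block
        acc_m = np.sqrt(acc_m)
        acc_m1 = np.sqrt(acc_m1)
    return acc_m, acc_m1


def sample_entropy(x, params: SampEnParams = SampEnParams()) -> SampEnResult:
    """Sample entropy of a 1-D series.

    Counts ordered pairs ``i != j`` of length-``m`` and length-``m+1``
    templates whose distance is <= ``r_multiplier * SD(x)`` and returns
    ``-ln(count_m1 / count_m)``.

    Degenerate cases: ``SD(x) == 0`` returns 0 with ``degenerate=True``;
    a zero count at either length returns ``nan`` with ``degenerate=True``.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = params.m
    if x.size < m + 2:
        raise ValueError(
            f"series of length {x.size} is too short for m={m} "
            f"(need at least {m + 2} samples)"
        )
    sd = float(x.std())
    n_templates = x.size - m
    n_pairs = n_templates * (n_templates - 1)
    if sd == 0.0:
        return SampEnResult(0.0, n_pairs, n_pairs, 0.0, degenerate=True)
    r = params.r_multiplier * sd
    d_m, d_m1 = _template_distance_matrices(x, m, params.distance)
    off_diag = ~np.eye(n_templates, dtype=bool)
    a = int(np.count_nonzero((d_m <= r) & off_diag))
    b = int(np.count_nonzero((d_m1 <= r) & off_diag))
    if a == 0 or b == 0:
        return SampEnResult(float("nan"), a, b, sd, degenerate=True)
    return SampEnResult(float(-np.log(b / a)), a, b, sd, degenerate=False)


def sample_entropy_batch(X, params: SampEnParams = SampEnParams()):
    """Sample entropy of each row of a 2-D array ``(n_series, n_samples)``.

    Vectorized equivalent of calling :func:`sample_entropy` per row; returns
    ``(values, degenerate)`` float/bool arrays of length ``n_series`` with
    nan where the estimate is undefined.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_series, n_samples)")
    m = params.m
    n_series, n = X.shape
    if n < m + 2:
        raise ValueError(
            f"series of length {n} too short for m={m} (need >= {m + 2})"
        )
    nt = n - m
    values = np.empty(n_series)
    degenerate = np.zeros(n_series, dtype=bool)
    sds = X.std(axis=1)
    flat = sds == 0.0
    values[flat] = 0.0
    degenerate[flat] = True
    idx = np.nonzero(~flat)[0]
    if idx.size:
        # broadcast pairwise sample differences per series, then reduce over
        # the m (and m+1) diagonal-shifted blocks
        d0 = np.abs(X[idx, :, None] - X[idx, None, :])
        if params.distance == "euclidean":
            d0 = d0**2
        acc_m = d0[:, :nt, :nt].copy()
        for k in range(1, m):
            block = d0[:, k : k + nt, k : k + nt]
            if params.distance == "chebyshev":
                np.maximum(acc_m, block, out=acc_m)
            else:
                acc_m += block
        block = d0[:, m : m + nt, m : m + nt]
        if params.distance == "chebyshev":
            acc_m1 = np.maximum(acc_m, block)
        else:
            acc_m1 = np.sqrt(acc_m + block)
            acc_m = np.sqrt(acc_m)
        r = (params.r_multiplier * sds[idx])[:, None, None]
        off = ~np.eye(nt, dtype=bool)
        a = np.count_nonzero((acc_m <= r) & off, axis=(1, 2))
        b = np.count_nonzero((acc_m1 <= r) & off, axis=(1, 2))
        bad = (a == 0) | (b == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = -np.log(b / a)
        v[bad] = np.nan
        values[idx] = v
        degenerate[idx] = bad
    return values, degenerate


def sliding_window_entropy(
    channel,
    schedule: WindowSchedule = WindowSchedule(),
    params: SampEnParams = SampEnParams(),
    t0_sample: int = 0,
):
    """Sample entropy in each scheduled window of a stimulus-locked channel.

    Parameters
    ----------
    channel : 1-D array
        Single-channel samples; index ``t0_sample`` is stimulus onset.
    schedule, params
        Window schedule and estimator configuration.  The tolerance is
        recomputed in every window from that window's own SD.
    t0_sample : int
        Sample index of stimulus onset within ``channel``.

    Returns
    -------
    (centers_ms, values, degenerate)
        Window centers in ms post-stimulus, the sampEn value per window
        (nan where undefined), and the degenerate flags.
    """
    channel = np.asarray(channel, dtype=float).ravel()
    wlen = schedule.window_samples
    if wlen < params.m + 2:
        raise ValueError(
            f"window of {wlen} samples too short for m={params.m}"
        )
    centers = schedule.centers_ms
    starts = np.array(
        [schedule.start_index(c, t0_sample) for c in centers], dtype=int
    )
    if starts.min() < 0 or (starts.max() + wlen) > channel.size:
        lo = starts.min()
        hi = starts.max() + wlen
        raise ValueError(
            "epoch too short for window schedule: needs sample span "
            f"[{lo}, {hi}) but channel has {channel.size} samples "
            f"(t0 at {t0_sample})"
        )
    windows = np.stack([channel[s : s + wlen] for s in starts])
    values, degenerate = sample_entropy_batch(windows, params)
    return centers, values, degenerate
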