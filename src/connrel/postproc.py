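"""Post-processing variants defining the motion-handling multiverse.

Implements the stages an XCP-D-style connectivity pipeline applies to an
already-parcellated run: non-steady-state volume discard, framewise
displacement (FD), FD-threshold scrubbing, 36-parameter confound regression
(32 without global signal regression), and zero-phase Butterworth band-pass
filtering.

The five canonical pipeline variants are: ``primary`` (GSR, no scrubbing),
``no-gsr``, and three scrubbed variants at FD thresholds 2.0 / 1.0 / 0.5 mm
(all with GSR).  :func:`run_pipeline` applies, in order: volume discard;
linear interpolation of to-be-censored volumes (so neither the filter nor
the regression sees suprathreshold-volume artifacts or gaps); zero-phase
band-pass of the signals *and* of the continuous confound regressors
(regressing unfiltered confounds from filtered data would reintroduce
out-of-band variance); confound regression; removal of the censored volumes.
The alternative hard censor-before-filter order (dropping volumes first and
filtering the concatenated series) is available via
``PipelineVariant.censor_before_filter``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .cohort import ParcellatedRun

#: Head-radius (mm) used to convert rotation increments to arc length in the
#: Power FD convention.
DEFAULT_HEAD_RADIUS_MM = 50.0


@dataclass(frozen=True)
class FDTrace:
    """Per-volume framewise displacement, in mm; index 0 is 0 by convention."""

    values: np.ndarray
    radius_mm: float = DEFAULT_HEAD_RADIUS_MM

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("FD trace must be one-dimensional")
        if self.values[0] != 0.0:
            raise ValueError("FD at index 0 must be 0 (no predecessor)")


@dataclass(frozen=True)
class PipelineVariant:
    """One cell of the motion-handling multiverse."""

    name: str
    use_gsr: bool = True
    scrub_threshold_mm: float | None = None
    bandpass_hz: tuple[float, float] = (0.01, 0.08)
    butterworth_order: int = 2
    n_discard: int = 4
    censor_before_filter: bool = False

    def __post_init__(self) -> None:
        if self.scrub_threshold_mm is not None and self.scrub_threshold_mm <= 0:
            raise ValueError("scrub threshold must be positive")
        low, high = self.bandpass_hz
        if not 0 < low < high:
            raise ValueError("invalid band-pass corner frequencies")


CANONICAL_VARIANTS: dict[str, PipelineVariant] = {
    "primary": PipelineVariant("primary"),
    "no-gsr": PipelineVariant("no-gsr", use_gsr=False),
    "scrub-2.0": PipelineVariant("scrub-2.0", scrub_threshold_mm=2.0),
    "scrub-1.0": PipelineVariant("scrub-1.0", scrub_threshold_mm=1.0),
    "scrub-0.5": PipelineVariant("scrub-0.5", scrub_threshold_mm=0.5),
}

#: CLI-friendly aliases.
VARIANT_ALIASES = {
    "primary": "primary",
    "nogsr": "no-gsr",
    "no-gsr": "no-gsr",
    "fd2.0": "scrub-2.0",
    "fd1.0": "scrub-1.0",
    "fd0.5": "scrub-0.5",
    "scrub-2.0": "scrub-2.0",
    "scrub-1.0": "scrub-1.0",
    "scrub-0.5": "scrub-0.5",
}


def get_variant(name: str) -> PipelineVariant:
    try:
        return CANONICAL_VARIANTS[VARIANT_ALIASES[name]]
    except KeyError:
        raise KeyError(
            f"unknown pipeline variant {name!r}; choose from {sorted(VARIANT_ALIASES)}"
        ) from None


@dataclass(frozen=True)
class CensorMask:
    """Volumes retained after scrubbing, with bookkeeping for report tables."""

    keep: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "keep", np.asarray(self.keep, dtype=bool))

    @property
    def n_scrubbed(self) -> int:
        return int(np.sum(~self.keep))

    @property
    def n_retained(self) -> int:
        return int(np.sum(self.keep))

    @property
    def retained_minutes(self) -> float:
        return self.n_retained * self.tr_seconds / 60.0


@dataclass
class CleanedRun:
    """Output of :func:`run_pipeline`: denoised, censored signals."""

    run: ParcellatedRun
    variant: PipelineVariant
    signals: np.ndarray  # retained volumes x N
    mask: CensorMask
    fd: FDTrace


# --------------------------------------------------------------------------- #
# stages
# --------------------------------------------------------------------------- #


def discard_nonsteady(run: ParcellatedRun, n: int = 4) -> ParcellatedRun:
    """Drop the first ``n`` non-steady-state volumes from every trace."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return run
    if run.n_volumes <= n:
        raise ValueError(f"cannot discard {n} of {run.n_volumes} volumes")
    return replace(
        run,
        signals=run.signals[n:],
        motion_params=run.motion_params[n:],
        nuisance=run.nuisance[n:],
    )


def compute_fd(
    motion_params: np.ndarray, radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> FDTrace:
    """Power-convention framewise displacement.

    FD_t = sum |delta translation| + radius * sum |delta rotation|, with
    rotations in radians converted to arc length on a ``radius_mm`` sphere.
    """
    motion = np.asarray(motion_params, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion parameters must be T x 6")
    deltas = np.abs(np.diff(motion, axis=0))
    fd = deltas[:, :3].sum(axis=1) + radius_mm * deltas[:, 3:].sum(axis=1)
    return FDTrace(np.concatenate([[0.0], fd]), radius_mm=radius_mm)


def make_censor_mask(
    fd: FDTrace, threshold_mm: float, tr_seconds: float
) -> CensorMask:
    """Censor volumes whose FD strictly exceeds the threshold."""
    if threshold_mm <= 0:
        raise ValueError("threshold must be positive")
    return CensorMask(keep=fd.values <= threshold_mm, tr_seconds=tr_seconds)


def build_confounds(run: ParcellatedRun, use_gsr: bool = True) -> np.ndarray:
    """Assemble the 36-parameter (or 32 without GSR) confound matrix.

    Base set: 6 motion parameters + global (if ``use_gsr``) + WM + CSF means;
    plus backward-difference temporal derivatives (first row zero-filled) of
    the base set; plus squares of all of those; then a linear trend and an
    intercept column are appended (total 38 or 34 columns).
    """
    core = _confound_core(run, use_gsr)
    t = core.shape[0]
    trend = np.linspace(-1.0, 1.0, t)
    return np.column_stack([core, trend, np.ones(t)])


def _confound_core(run: ParcellatedRun, use_gsr: bool) -> np.ndarray:
    """The 36 (or 32) continuous confound columns, without trend/intercept."""
    tissue = run.nuisance if use_gsr else run.nuisance[:, 1:]
    base = np.column_stack([run.motion_params, tissue])
    if base.shape[0] != run.signals.shape[0]:  # pragma: no cover - same object
        raise ValueError("confound traces not aligned with signals")
    derivs = np.vstack([np.zeros((1, base.shape[1])), np.diff(base, axis=0)])
    return np.column_stack([base, derivs, base**2, derivs**2])


def regress_confounds(signals: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Per-node OLS residuals of ``signals`` against the confound columns.

    Rank-deficient confound matrices are handled by the minimum-norm
    least-squares solution (equivalent to dropping collinear columns); a
    warning is emitted.
    """
    signals = np.asarray(signals, dtype=float)
    confounds = np.asarray(confounds, dtype=float)
    t, p = confounds.shape
    if signals.shape[0] != t:
        raise ValueError("signals and confounds have different lengths")
    if p >= t:
        raise ValueError("need more time points than confound columns")
    # all-zero columns (e.g. motion-free runs) carry no information; drop
    # them silently so they do not masquerade as collinearity
    nonzero = np.any(confounds != 0.0, axis=0)
    confounds = confounds[:, nonzero]
    p = confounds.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(confounds, signals, rcond=None)
    if rank < p:
        warnings.warn(
            f"confound matrix is rank deficient ({rank} < {p}); "
            "collinear columns are effectively dropped",
            stacklevel=2,
        )
    return signals - confounds @ beta


def bandpass(
    signals: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 2,
    tr_seconds: float = 2.0,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass, per node."""
    fs = 1.0 / tr_seconds
    nyquist = fs / 2.0
    if not 0 < low_hz < high_hz < nyquist:
        raise ValueError("need 0 < low < high < Nyquist")
    b, a = sps.butter(order, [low_hz, high_hz], btype="band", fs=fs)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if signals.shape[0] <= padlen:
        raise ValueError(f"need more than {padlen} volumes for filter padding")
    return sps.filtfilt(b, a, signals, axis=0)


def run_pipeline(run: ParcellatedRun, variant: PipelineVariant) -> CleanedRun:
    """Apply one full post-processing variant to a run.

    Raises ``ValueError`` if fewer than 10 volumes survive censoring.
    """
    post = discard_nonsteady(run, variant.n_discard)
    fd = compute_fd(post.motion_params)
    if variant.scrub_threshold_mm is None:
        mask = CensorMask(np.ones(post.n_volumes, dtype=bool), post.tr_seconds)
    else:
        mask = make_censor_mask(fd, variant.scrub_threshold_mm, post.tr_seconds)
    if mask.n_retained < 10:
        raise ValueError(
            f"unusable run {post.subject_id} ses-{post.session}: "
            f"only {mask.n_retained} volumes retained"
        )
    core = _confound_core(post, use_gsr=variant.use_gsr)
    low, high = variant.bandpass_hz
    order, tr = variant.butterworth_order, post.tr_seconds

    def _filter(x: np.ndarray) -> np.ndarray:
        return bandpass(x, low, high, order, tr)

    t = post.n_volumes
    trend_intercept = np.column_stack([np.linspace(-1.0, 1.0, t), np.ones(t)])
    if variant.censor_before_filter:
        keep = mask.keep
        design = np.column_stack(
            [_filter(core[keep]), trend_intercept[keep]]
        )
        cleaned = regress_confounds(_filter(post.signals[keep]), design)
    else:
        signals = _filter(_interpolate_censored(post.signals, mask.keep))
        confs = _filter(_interpolate_censored(core, mask.keep))
        design = np.column_stack([confs, trend_intercept])
        residuals = regress_confounds(signals, design)
        cleaned = residuals[mask.keep]
    return CleanedRun(run=post, variant=variant, signals=cleaned, mask=mask, fd=fd)


def _interpolate_censored(signals: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Linearly interpolate censored volumes from retained neighbours.

    Keeps the series contiguous for zero-phase filtering without letting
    censored-volume artifacts bleed into retained volumes; a no-op when the
    mask keeps everything.
    """
    if keep.all():
        return signals
    t = np.arange(signals.shape[0])
    out = signals.copy()
    kept_t = t[keep]
    for j in range(signals.shape[1]):
        out[~keep, j] = np.interp(t[~keep], kept_t, signals[keep, j])
    return out
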