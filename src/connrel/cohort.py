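"""Synthetic two-session resting-state cohorts with known reliability structure.

Real test-retest connectome studies measure, per subject and scan session, a
parcellated BOLD signal matrix.  The generator here emulates that design at the
statistical level: every subject owns a latent node-node correlation matrix;
each session realizes a perturbed copy of it; signals are stationary
multivariate normal draws from the session matrix, contaminated with smooth
nuisance components (global / white-matter / CSF) and motion-locked spike
artifacts.  Between-subject and within-subject (between-session) variation are
calibrated on the Fisher-z scale so the generative edge-level intraclass
correlation is known in closed form — which is what makes every downstream
reliability estimate testable without MRI data.

Calibration model
-----------------
Write ``z_ijs`` for the Fisher-z connectivity of edge *j*, subject *i*,
session *s*.  The generator produces

    z_ijs = z0_j + b_ij + w_ijs

with ``Var(b) = sigma_b^2`` (stable individual differences) and
``Var(w) = sigma_w^2`` (session-to-session wobble).  Both levels are realized
by resampling a correlation matrix from a Wishart distribution centred on the
parent matrix: the sample correlation of ``m`` multivariate-normal draws has
Fisher-z variance ``~ 1/(m - 3)`` around the parent value regardless of the
edge's strength, so ``sigma^2`` maps to degrees of freedom ``m = 3 + 1/sigma^2``
and every intermediate matrix is a valid correlation matrix by construction.
Estimating connectivity from T volumes adds a third, irreducible noise level
with variance ``~ 1/(T - 3)``; the generative ICC of the *measured* edge is

    rho_obs = sigma_b^2 / (sigma_b^2 + sigma_w^2 + 1/(T - 3)).

Both the latent ratio and ``rho_obs`` are reported in the ground-truth record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

GROUP_A = "groupA"
GROUP_B = "groupB"

#: Default total latent edge standard deviation (z units) split between the
#: subject and session levels when ``target_edge_icc`` is set.  Chosen so that
#: the T=296 estimation noise (sd ~0.058 z) stays a small fraction of the
#: latent variation, as it is for stable individual differences in real
#: connectomes.
DEFAULT_LATENT_SD = 0.30


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class Parcellation:
    """Node list with canonical-network assignments and coverage fractions."""

    node_ids: tuple[str, ...]
    network_of: dict[str, str]
    coverage_of: dict[str, float]
    atlas_name: str = "fixture"

    def __post_init__(self) -> None:
        missing = [n for n in self.node_ids if n not in self.network_of]
        if missing:
            raise ValueError(f"nodes without a network label: {missing[:5]}")
        for net, size in zip(*np.unique(self.labels, return_counts=True)):
            if size < 1:  # pragma: no cover - unique() cannot yield 0
                raise ValueError(f"empty network {net}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def labels(self) -> np.ndarray:
        """Network label per node, in node order."""
        return np.asarray([self.network_of[n] for n in self.node_ids])

    @property
    def networks(self) -> tuple[str, ...]:
        """Network labels in first-appearance order."""
        seen: dict[str, None] = {}
        for n in self.node_ids:
            seen.setdefault(self.network_of[n], None)
        return tuple(seen)

    @property
    def network_sizes(self) -> dict[str, int]:
        labels = self.labels
        return {net: int(np.sum(labels == net)) for net in self.networks}

    @property
    def coverage(self) -> np.ndarray:
        return np.asarray([self.coverage_of[n] for n in self.node_ids], dtype=float)


@dataclass
class ParcellatedRun:
    """One subject-session signal matrix plus motion and nuisance traces.

    ``signals``: T x N BOLD-like values; ``motion_params``: T x 6 rigid-body
    parameters (3 translations in mm, 3 rotations in radians), row 0 being the
    reference position; ``nuisance``: T x 3 columns (global, WM, CSF means).
    """

    subject_id: str
    session: int
    group: str
    signals: np.ndarray
    motion_params: np.ndarray
    nuisance: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.motion_params = np.asarray(self.motion_params, dtype=float)
        self.nuisance = np.asarray(self.nuisance, dtype=float)
        t = self.signals.shape[0]
        if t < 8:
            raise ValueError("need at least 8 volumes")
        if self.session not in (1, 2):
            raise ValueError("session must be 1 or 2")
        if self.motion_params.shape != (t, 6):
            raise ValueError("motion_params must be T x 6")
        if self.nuisance.shape != (t, 3):
            raise ValueError("nuisance must be T x 3 (global, WM, CSF)")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.signals.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.signals.shape[1]


@dataclass
class CohortSpec:
    """Configuration of a two-session synthetic cohort.

    ``target_edge_icc``, when given, overrides ``between_subject_sd`` /
    ``within_subject_sd`` keeping their total variance, so that
    sigma_b^2 / (sigma_b^2 + sigma_w^2) equals the target exactly.
    """

    n_subjects_per_group: int | dict[str, int] | None = None
    n_volumes: int = 300
    tr_seconds: float = 2.0
    n_nodes: int | None = None
    network_sizes: list[int] | None = None
    within_block_corr: float = 0.45
    between_block_corr: float = 0.12
    between_subject_sd: float = 0.25
    within_subject_sd: float = 0.17
    target_edge_icc: float | None = None
    motion_fd_mean_by_group: dict[str, float] = field(
        default_factory=lambda: {GROUP_A: 0.32, GROUP_B: 0.24}
    )
    motion_fd_sd_by_group: dict[str, float] = field(
        default_factory=lambda: {GROUP_A: 0.23, GROUP_B: 0.11}
    )
    spike_rate: float = 0.10
    spike_gain: float = 2.0
    nuisance_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"global": 0.5, "wm": 0.3, "csf": 0.3}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group is None:
            self.n_subjects_per_group = {GROUP_A: 45, GROUP_B: 41}
        if isinstance(self.n_subjects_per_group, int):
            self.n_subjects_per_group = {
                g: self.n_subjects_per_group for g in self.motion_fd_mean_by_group
            }
        if self.n_volumes < 8:
            raise ValueError("n_volumes must be >= 8")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0.0 <= self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must be in [0, 1)")
        if not 0.0 <= self.between_block_corr < 1.0:
            raise ValueError("between_block_corr must be in [0, 1)")
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise ValueError("edge-level sds must be nonnegative")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ValueError("spike_rate must be in [0, 1]")
        for g, fd in self.motion_fd_mean_by_group.items():
            if fd < 0:
                raise ValueError(f"negative FD mean for {g}")
        if self.target_edge_icc is not None:
            rho = float(self.target_edge_icc)
            if not 0.0 <= rho < 1.0:
                raise ValueError("target_edge_icc must be in [0, 1)")
            total_var = self.between_subject_sd**2 + self.within_subject_sd**2
            if total_var == 0.0:
                total_var = DEFAULT_LATENT_SD**2
            self.between_subject_sd = float(np.sqrt(rho * total_var))
            self.within_subject_sd = float(np.sqrt((1.0 - rho) * total_var))

    @property
    def groups(self) -> tuple[str, ...]:
        assert isinstance(self.n_subjects_per_group, dict)
        return tuple(self.n_subjects_per_group)


@dataclass
class GroundTruth:
    """Generative record accompanying a simulated cohort."""

    template_corr: np.ndarray
    sigma_b: float
    sigma_w: float
    m_subject: int | None
    m_session: int | None
    latent_edge_icc: float
    fd_mean_by_subject: dict[str, float]
    #: subject-level latent Fisher-z matrices (subject -> N x N), kept only
    #: for small parcellations
    subject_latent_z: dict[str, np.ndarray] | None = None
    #: per-session latent Fisher-z matrices ((subject, session) -> N x N)
    session_latent_z: dict[tuple[str, int], np.ndarray] | None = None

    def expected_observed_icc(self, n_volumes: int) -> float:
        """Generative ICC of an edge measured from ``n_volumes`` samples."""
        sb2 = 0.0 if self.m_subject is None else 1.0 / (self.m_subject - 3)
        sw2 = 0.0 if self.m_session is None else 1.0 / (self.m_session - 3)
        samp = 1.0 / (n_volumes - 3)
        denom = sb2 + sw2 + samp
        return sb2 / denom if denom > 0 else 0.0


# --------------------------------------------------------------------------- #
# parcellations
# --------------------------------------------------------------------------- #


def make_parcellation(
    n_nodes: int,
    network_sizes: list[int],
    atlas_name: str = "fixture",
    coverage: dict[str, float] | None = None,
) -> Parcellation:
    """Build a parcellation with contiguous network blocks.

    Nodes are named ``n1..nN``; networks ``net01..netK`` assigned contiguously.
    All coverage fractions default to 1.0.
    """
    sizes = [int(s) for s in network_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("network sizes must be positive")
    if sum(sizes) != n_nodes:
        raise ValueError(
            f"network_sizes sum to {sum(sizes)}, expected n_nodes={n_nodes}"
        )
    node_ids = tuple(f"n{i + 1}" for i in range(n_nodes))
    network_of: dict[str, str] = {}
    i = 0
    for k, size in enumerate(sizes):
        label = f"net{k + 1:02d}"
        for _ in range(size):
            network_of[node_ids[i]] = label
            i += 1
    coverage_of = {n: 1.0 for n in node_ids}
    if coverage:
        coverage_of.update(coverage)
    return Parcellation(node_ids, network_of, coverage_of, atlas_name)


#: Desk-scale stand-ins mirroring the node/network diversity of widely used
#: atlases (Schaefer 100/400, Power, Gordon, Brainnetome, Glasser).  Sizes are
#: generated deterministically; the two largest presets are optional extras.
FIXTURE_ATLAS_SPECS: dict[str, tuple[int, int]] = {
    "schaefer100-like": (100, 17),
    "power231-like": (231, 12),
    "gordon266-like": (266, 12),
    "brainnetome274-like": (274, 19),
    "glasser360-like": (360, 12),
    "schaefer400-like": (400, 17),
}

OPTIONAL_ATLAS_SPECS: dict[str, tuple[int, int]] = {
    "schaefer700-like": (700, 17),
    "schaefer1000-like": (1000, 17),
}


def _split_sizes(n_nodes: int, n_networks: int, seed: int) -> list[int]:
    """Deterministic uneven partition of n_nodes into n_networks sizes >= 2."""
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.full(n_networks, 3.0))
    sizes = np.maximum(2, np.floor(weights * n_nodes).astype(int))
    # largest-remainder style fixup to hit the exact total
    while sizes.sum() > n_nodes:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_nodes:
        sizes[np.argmin(sizes)] += 1
    return [int(s) for s in sizes]


def fixture_atlases(include_optional: bool = False) -> list[Parcellation]:
    """The six (or eight) deterministic fixture parcellations."""
    specs = dict(FIXTURE_ATLAS_SPECS)
    if include_optional:
        specs.update(OPTIONAL_ATLAS_SPECS)
    out = []
    for i, (name, (n_nodes, n_networks)) in enumerate(specs.items()):
        sizes = _split_sizes(n_nodes, n_networks, seed=7_654_000 + i)
        out.append(make_parcellation(n_nodes, sizes, atlas_name=name))
    return out


# --------------------------------------------------------------------------- #
# generative machinery
# --------------------------------------------------------------------------- #


def _block_template(parcellation: Parcellation, within: float, between: float) -> np.ndarray:
    labels = parcellation.labels
    same = labels[:, None] == labels[None, :]
    c = np.where(same, within, between)
    np.fill_diagonal(c, 1.0)
    eigmin = float(np.linalg.eigvalsh(c).min())
    if eigmin <= 0:
        raise ValueError(
            f"block template is not positive definite (min eigenvalue {eigmin:.3g})"
        )
    return c


def _corr_factor(c: np.ndarray) -> np.ndarray:
    """Lower-triangular-ish factor L with L @ L.T ~= c, robust to singularity."""
    try:
        return np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        # Wishart-derived correlation matrices can be exactly singular
        # (rank = dof); fall back to an eigenvalue square root.
        logger.debug("singular correlation matrix; using eigenvalue factor")
        vals, vecs = np.linalg.eigh(c)
        vals = np.clip(vals, 0.0, None)
        return vecs * np.sqrt(vals)


def _sample_corr(parent: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Correlation matrix of the scatter of m draws from N(0, parent)."""
    lfac = _corr_factor(parent)
    x = rng.standard_normal((m, parent.shape[0])) @ lfac.T
    s = x.T @ x
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)


def _sigma_to_dof(sigma: float) -> int | None:
    """Degrees of freedom whose sample-correlation z-noise has sd ``sigma``."""
    if sigma == 0.0:
        return None
    return max(5, int(round(3.0 + 1.0 / sigma**2)))


def _nuisance_trace(t: int, tr: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-sd low-frequency sinusoid-plus-AR(1) physiological drift."""
    from scipy.signal import lfilter

    time = np.arange(t) * tr
    freq = rng.uniform(0.01, 0.03)
    phase = rng.uniform(0, 2 * np.pi)
    sinus = np.sin(2 * np.pi * freq * time + phase)
    ar = lfilter([1.0], [1.0, -0.95], rng.standard_normal(t))
    ar = (ar - ar.mean()) / max(ar.std(), 1e-12)
    trace = sinus + 0.5 * ar
    return (trace - trace.mean()) / max(trace.std(), 1e-12)


# --------------------------------------------------------------------------- #
# motion injection
# --------------------------------------------------------------------------- #


def _inject_motion_rng(
    run: ParcellatedRun,
    fd_mean: float,
    spike_rate: float,
    rng: np.random.Generator,
    spike_gain: float = 2.0,
    radius_mm: float = 50.0,
) -> ParcellatedRun:
    t, n = run.signals.shape
    if fd_mean < 0:
        raise ValueError("fd_mean must be nonnegative")
    if not 0.0 <= spike_rate <= 1.0:
        raise ValueError("spike_rate must be in [0, 1]")
    if fd_mean == 0.0:
        fd = np.zeros(t)
    else:
        # exponential per-frame FD: realistic spiky motion with E[FD] = fd_mean
        fd = np.concatenate([[0.0], rng.gamma(shape=1.0, scale=fd_mean, size=t - 1)])
    # split each frame's FD across the six parameters; rotations converted
    # back from arc length on the radius_mm sphere
    weights = rng.dirichlet(np.ones(6), size=t)
    signs = rng.choice([-1.0, 1.0], size=(t, 6))
    increments = weights * signs * fd[:, None]
    increments[:, 3:] /= radius_mm
    increments[0] = 0.0
    motion = np.cumsum(increments, axis=0)

    signals = run.signals.copy()
    if spike_rate > 0.0 and fd_mean > 0.0:
        spike_mask = rng.random(t) < spike_rate
        spike_mask[0] = False
        n_spikes = int(spike_mask.sum())
        # each motion event corrupts the volume with its own spatial pattern
        # (amplitude locked to that volume's FD); a single shared pattern
        # would be temporally rank-one and almost fully absorbed by GSR
        patterns = rng.standard_normal((n_spikes, n))
        signals[spike_mask] += spike_gain * fd[spike_mask, None] * patterns
    return replace(run, signals=signals, motion_params=motion)


def inject_motion(
    run: ParcellatedRun,
    fd_mean: float,
    spike_rate: float,
    seed: int,
    spike_gain: float = 2.0,
    radius_mm: float = 50.0,
) -> ParcellatedRun:
    """Overwrite a run's motion trace and add motion-locked spike artifacts.

    Per-frame framewise displacement is exponential with mean ``fd_mean``
    (frame 0 is the reference, FD 0); each frame's displacement is split
    randomly across the six rigid-body parameters and integrated into
    positions.  With probability ``spike_rate`` a frame receives an additive
    rank-one signal artifact with amplitude ``spike_gain * FD``.
    """
    return _inject_motion_rng(
        run, fd_mean, spike_rate, np.random.default_rng(seed), spike_gain, radius_mm
    )


# --------------------------------------------------------------------------- #
# cohort simulation
# --------------------------------------------------------------------------- #


def simulate_cohort(
    spec: CohortSpec,
    parcellation: Parcellation,
    store_latents: bool | None = None,
) -> tuple[list[ParcellatedRun], GroundTruth]:
    """Generate the two-session cohort defined by ``spec``.

    Returns all runs (2 sessions x all subjects, session-major per subject)
    plus the generative ground truth.  Reproducible under ``spec.seed``.
    ``store_latents`` keeps per-subject/session latent z matrices in the
    ground-truth record (defaults to True for parcellations up to 128 nodes).
    """
    n = parcellation.n_nodes
    if spec.n_nodes is not None and spec.n_nodes != n:
        raise ValueError(
            f"spec.n_nodes={spec.n_nodes} does not match parcellation ({n})"
        )
    if spec.network_sizes is not None and list(
        parcellation.network_sizes.values()
    ) != list(spec.network_sizes):
        raise ValueError("spec.network_sizes does not match parcellation")
    if store_latents is None:
        store_latents = n <= 128

    rng = np.random.default_rng(spec.seed)
    template = _block_template(
        parcellation, spec.within_block_corr, spec.between_block_corr
    )
    m_b = _sigma_to_dof(spec.between_subject_sd)
    m_w = _sigma_to_dof(spec.within_subject_sd)
    sb2 = spec.between_subject_sd**2
    sw2 = spec.within_subject_sd**2
    latent_icc = sb2 / (sb2 + sw2) if sb2 + sw2 > 0 else 0.0

    amp = {"global": 0.0, "wm": 0.0, "csf": 0.0}
    amp.update(spec.nuisance_amplitudes)

    runs: list[ParcellatedRun] = []
    fd_by_subject: dict[str, float] = {}
    subj_latent: dict[str, np.ndarray] = {}
    sess_latent: dict[tuple[str, int], np.ndarray] = {}
    t = spec.n_volumes

    with np.errstate(divide="ignore"):
        template_z = np.arctanh(np.clip(template, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(template_z, 0.0)

    for group in spec.groups:
        n_subj = spec.n_subjects_per_group[group]  # type: ignore[index]
        fd_mean = spec.motion_fd_mean_by_group.get(group, 0.0)
        fd_sd = spec.motion_fd_sd_by_group.get(group, 0.6 * fd_mean)
        for i in range(n_subj):
            subject = f"sub-{group}{i + 1:03d}"
            c_subj = template if m_b is None else _sample_corr(template, m_b, rng)
            if fd_mean == 0.0:
                fd_subject = 0.0
            elif fd_sd == 0.0:
                fd_subject = fd_mean
            else:
                shape = (fd_mean / fd_sd) ** 2
                fd_subject = float(rng.gamma(shape, fd_mean / shape))
            fd_by_subject[subject] = fd_subject
            if store_latents:
                subj_latent[subject] = _matrix_z(c_subj)
            for session in (1, 2):
                c_sess = c_subj if m_w is None else _sample_corr(c_subj, m_w, rng)
                if store_latents:
                    sess_latent[(subject, session)] = _matrix_z(c_sess)
                lfac = _corr_factor(c_sess)
                signals = rng.standard_normal((t, n)) @ lfac.T
                traces = {
                    name: (
                        _nuisance_trace(t, spec.tr_seconds, rng)
                        if amp[name] > 0.0
                        else np.zeros(t)
                    )
                    for name in ("global", "wm", "csf")
                }
                for name in ("global", "wm", "csf"):
                    if amp[name] > 0.0:
                        loadings = rng.uniform(0.8, 1.2, size=n)
                        signals += amp[name] * np.outer(traces[name], loadings)
                run = ParcellatedRun(
                    subject_id=subject,
                    session=session,
                    group=group,
                    signals=signals,
                    motion_params=np.zeros((t, 6)),
                    nuisance=np.zeros((t, 3)),
                    tr_seconds=spec.tr_seconds,
                )
                run = _inject_motion_rng(
                    run, fd_subject, spec.spike_rate, rng, spec.spike_gain
                )
                # measured nuisance traces: the realized global mean (so GSR
                # sees artifacts too) and the latent tissue drifts
                nuisance = np.column_stack(
                    [
                        run.signals.mean(axis=1),
                        amp["wm"] * traces["wm"],
                        amp["csf"] * traces["csf"],
                    ]
                )
                run.nuisance = nuisance
                runs.append(run)

    gt = GroundTruth(
        template_corr=template,
        sigma_b=spec.between_subject_sd,
        sigma_w=spec.within_subject_sd,
        m_subject=m_b,
        m_session=m_w,
        latent_edge_icc=latent_icc,
        fd_mean_by_subject=fd_by_subject,
        subject_latent_z=subj_latent if store_latents else None,
        session_latent_z=sess_latent if store_latents else None,
    )
    return runs, gt


def _matrix_z(c: np.ndarray) -> np.ndarray:
    z = np.arctanh(np.clip(c, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(z, 0.0)
    return z
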