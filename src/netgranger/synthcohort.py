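"""Synthetic two-group cohorts with known directed-coupling ground truth.

Emulates the study design the analysis assumes: two groups of subjects
(group A, "term-like"; group B, "VPT-like"), each contributing a k-channel
band-limited network time course sampled every 2 s, a 6-parameter head
realignment series, and perinatal covariates (gestational age in weeks, a
0/1/2 neonatal ultrasound classification, an executive-function score).
Group B's directed coupling on designated edges is attenuated
multiplicatively, so every downstream stage — spectra, GPDC, group
comparison, topology classification, moderation — can be validated against
a known generating model without any external data.

Covariates reproduce two qualitative features of very-preterm cohorts:
gestational age and ultrasound abnormality are negatively dependent, and
the executive-function score carries a configurable coupling-by-gestation
interaction so moderation recovery is testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .gpdc import VARModel, spectral_radius

__all__ = [
    "Edge",
    "CouplingSpec",
    "Subject",
    "Cohort",
    "build_stable_var",
    "random_coupling_spec",
    "random_stable_models",
    "simulate_timecourses",
    "generate_cohort",
    "generate_realignment",
    "generate_component_maps",
    "save_cohort",
    "load_cohort",
]

GROUP_A = "A"  # term-like reference group
GROUP_B = "B"  # VPT-like group with attenuated coupling

STABILITY_TARGET_RADIUS = 0.95
DEFAULT_BURNIN = 500


class Edge(NamedTuple):
    """A directed coupling source -> target at a given lag.

    Channel indices are 0-based; ``coefficient`` is the VAR entry
    a_{target,source}^{(lag)}.
    """

    source: int
    target: int
    lag: int
    coefficient: float


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth coupling structure of the generating VAR.

    ``attenuation`` maps a group label to the multiplicative factor in
    [0, 1] applied to each edge's coefficient for that group: either one
    scalar for all edges or a per-edge sequence aligned with ``edges``.
    """

    n_channels: int = 6
    order: int = 1
    edges: tuple[Edge, ...] = ()
    noise_variances: tuple[float, ...] | None = None
    attenuation: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: {GROUP_A: 1.0, GROUP_B: 1.0}
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "edges", tuple(Edge(*e) for e in self.edges)
        )
        if self.noise_variances is None:
            object.__setattr__(
                self, "noise_variances", tuple(1.0 for _ in range(self.n_channels))
            )
        nv = np.asarray(self.noise_variances, dtype=float)
        if nv.size != self.n_channels or np.any(nv <= 0):
            raise ValueError("noise_variances must be n_channels positive values")
        for e in self.edges:
            if not np.isfinite(e.coefficient):
                raise ValueError(f"non-finite coefficient on edge {e}")
            if not (0 <= e.source < self.n_channels and 0 <= e.target < self.n_channels):
                raise ValueError(f"edge {e} references a channel out of range")
            if not (1 <= e.lag <= self.order):
                raise ValueError(f"edge {e} lag outside 1..order")
        for group, fac in self.attenuation.items():
            arr = np.atleast_1d(np.asarray(fac, dtype=float))
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"attenuation factors for group {group!r} outside [0, 1]")

    def edge_factors(self, group: str) -> np.ndarray:
        if group not in self.attenuation:
            raise KeyError(f"unknown group label {group!r}")
        fac = np.atleast_1d(np.asarray(self.attenuation[group], dtype=float))
        if fac.size == 1:
            return np.full(len(self.edges), fac[0])
        if fac.size != len(self.edges):
            raise ValueError("per-edge attenuation length must match number of edges")
        return fac


@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str
    timecourses: np.ndarray  # (k, T)
    realignment: np.ndarray  # (T, 6): x,y,z translations (mm), rotations (rad)
    covariates: dict  # ga_weeks, us_code, ef_score


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[Subject, ...]
    sampling_interval: float = 2.0

    def __post_init__(self) -> None:
        shapes = {s.timecourses.shape for s in self.subjects}
        if len(shapes) > 1:
            raise ValueError("all subjects must share k and T")
        groups = {s.group for s in self.subjects}
        if len(groups) != 2:
            raise ValueError("cohort must contain exactly two group labels")

    def group_subjects(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]

    @property
    def labels(self) -> list[str]:
        return [s.group for s in self.subjects]

    def covariate_table(self) -> pd.DataFrame:
        rows = [
            {"subject_id": s.subject_id, "group": s.group, **s.covariates}
            for s in self.subjects
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generating model
# ---------------------------------------------------------------------------

def build_stable_var(spec: CouplingSpec, group: str, seed: int | None = None) -> VARModel:
    """Construct the generating VAR for one group, stabilised if necessary.

    Edge coefficients are placed into the lag matrices, the group's
    attenuation factors applied multiplicatively, and — should the realised
    coefficient set have companion spectral radius >= the 0.95 target — all
    coefficients are rescaled by one uniform factor (found by bisection)
    until the radius hits the target.  Rescaling preserves the edge
    topology and is reported via the returned model's radius.

    ``seed`` is accepted for signature symmetry with the simulators; the
    construction itself is deterministic.
    """
    factors = spec.edge_factors(group)
    k, p = spec.n_channels, spec.order
    A = np.zeros((p, k, k))
    for e, fac in zip(spec.edges, factors):
        A[e.lag - 1, e.target, e.source] += e.coefficient * fac
    rho = spectral_radius(A) if len(spec.edges) else 0.0
    if rho >= STABILITY_TARGET_RADIUS:
        A = A * _uniform_stabilising_factor(A, STABILITY_TARGET_RADIUS)
    sigma = np.diag(np.asarray(spec.noise_variances, dtype=float))
    return VARModel(np.zeros(k), A, sigma, n_samples_fit=0)


def _uniform_stabilising_factor(A: np.ndarray, target: float) -> float:
    """Scalar c in (0, 1] with spectral_radius(c * A) = target, by bisection.

    Uniform scaling moves companion eigenvalues monotonically but (for
    p > 1) nonlinearly, so the factor is located numerically.
    """
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if spectral_radius(mid * A) < target:
            lo = mid
        else:
            hi = mid
    return lo


def random_coupling_spec(
    n_channels: int,
    order: int,
    seed: int,
    density: float = 0.3,
    coeff_scale: float = 0.5,
) -> CouplingSpec:
    """A random sparse coupling spec (off-diagonal edges plus AR diagonals).

    Used to build ensembles of random stable VAR systems for property
    checks; stabilisation in :func:`build_stable_var` guarantees the
    realised model is stationary whatever is drawn here.
    """
    rng = np.random.default_rng(seed)
    edges: list[Edge] = []
    for i in range(n_channels):  # own-history terms keep spectra non-trivial
        edges.append(Edge(i, i, 1, float(rng.uniform(0.2, 0.6))))
    for l in range(1, order + 1):
        for i in range(n_channels):
            for j in range(n_channels):
                if i != j and rng.random() < density:
                    edges.append(
                        Edge(j, i, l, float(rng.normal(0.0, coeff_scale)))
                    )
    variances = tuple(float(v) for v in rng.uniform(0.5, 2.0, size=n_channels))
    return CouplingSpec(
        n_channels=n_channels,
        order=order,
        edges=tuple(edges),
        noise_variances=variances,
    )


def random_stable_models(
    n_models: int,
    seed: int,
    k_range: tuple[int, int] = (2, 6),
    p_range: tuple[int, int] = (1, 5),
) -> list[VARModel]:
    """An ensemble of random stable VAR generators spanning channel counts
    ``k_range`` and orders ``p_range`` (inclusive), for property checks."""
    rng = np.random.default_rng(seed)
    models = []
    for _ in range(n_models):
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        p = int(rng.integers(p_range[0], p_range[1] + 1))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = random_coupling_spec(k, p, seed=sub_seed, density=0.5, coeff_scale=0.8)
        models.append(build_stable_var(spec, GROUP_A))
    return models


def simulate_timecourses(
    model: VARModel, T: int, burnin: int = DEFAULT_BURNIN, seed: int | None = None
) -> np.ndarray:
    """Simulate a (k, T) realisation of the VAR with Gaussian innovations.

    The recursion is seeded at zero and the first ``burnin`` samples are
    discarded; identical seeds give bitwise-identical output.
    """
    k, p = model.k, model.p
    if T < 10 * k * p:
        raise ValueError(f"T={T} too short: need T >= 10*k*p = {10 * k * p}")
    if burnin < 100:
        raise ValueError("burnin must be >= 100")
    if not model.is_stable():
        raise ValueError("refusing to simulate from an unstable model")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(
        model.residual_covariance
        + 1e-12 * np.eye(k) * np.trace(model.residual_covariance)
    )
    eps = rng.standard_normal((burnin + T, k)) @ chol.T
    out = np.zeros((burnin + T, k))
    v = model.intercept
    A = model.coefficients
    for t in range(burnin + T):
        acc = v + eps[t]
        for l in range(1, min(p, t) + 1):
            acc = acc + A[l - 1] @ out[t - l]
        out[t] = acc
    return out[burnin:].T.copy()


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: executive-function generating model: ef = b0 + b1*c + b2*ga + b3*c*(ga-35) + noise,
#: where c is the subject's realised coupling scale.  The negative interaction
#: makes the coupling-EF slope steepest at low gestational age.
DEFAULT_EF_MODEL = {"b0": 100.0, "b_coupling": 5.0, "b_ga": 0.5, "b_interaction": -1.0, "noise_sd": 2.0}


def generate_cohort(
    spec: CouplingSpec,
    n_per_group: tuple[int, int] = (23, 29),
    T: int = 256,
    seed: int = 0,
    burnin: int = DEFAULT_BURNIN,
    drift_scale: float = 0.02,
    ga_us_rank_corr: float = -0.6,
    ef_model: Mapping[str, float] = DEFAULT_EF_MODEL,
    coupling_jitter_sd: float = 0.05,
) -> Cohort:
    """Generate a two-group cohort with group-B-attenuated coupling.

    Per-subject noise streams are spawned deterministically from the master
    seed, so the cohort is reproducible subject-wise: subject s always
    receives the s-th spawned stream regardless of how earlier subjects'
    draws are consumed.

    Group sizes default to 23 (term-like) and 29 (VPT-like).  Gestational
    age and ultrasound code are drawn with a configurable negative rank
    dependence; the executive-function score follows a linear model with a
    coupling-by-gestation interaction (see ``DEFAULT_EF_MODEL``).
    """
    n_a, n_b = n_per_group
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    n_total = n_a + n_b
    streams = np.random.SeedSequence(seed).spawn(n_total + 1)
    cov_rng = np.random.default_rng(streams[-1])
    subjects = []
    for s in range(n_total):
        group = GROUP_A if s < n_a else GROUP_B
        rng = np.random.default_rng(streams[s])
        sub_seed = int(rng.integers(0, 2**31 - 1))
        # subject-level multiplicative jitter on the group's edge factors
        jitter = float(np.clip(rng.normal(1.0, coupling_jitter_sd), 0.5, 1.5))
        base = spec.edge_factors(group)
        sub_spec = replace(
            spec, attenuation={**dict(spec.attenuation), group: np.clip(base * jitter, 0, 1)}
        )
        model = build_stable_var(sub_spec, group)
        tc = simulate_timecourses(model, T, burnin=burnin, seed=sub_seed)
        rp = generate_realignment(T, drift_scale=drift_scale, spikes=(), seed=sub_seed + 1)
        coupling_scale = float(np.mean(sub_spec.edge_factors(group)))
        cov = _draw_covariates(group, coupling_scale, cov_rng, ga_us_rank_corr, ef_model)
        subjects.append(
            Subject(
                subject_id=f"sub-{s:03d}",
                group=group,
                timecourses=tc,
                realignment=rp,
                covariates=cov,
            )
        )
    return Cohort(subjects=tuple(subjects))


def _draw_covariates(
    group: str,
    coupling_scale: float,
    rng: np.random.Generator,
    ga_us_rank_corr: float,
    ef_model: Mapping[str, float],
) -> dict:
    if group == GROUP_A:
        ga = float(np.clip(rng.normal(40.0, 1.3), 37.0, 42.0))
        us = 0 if rng.random() < 0.95 else 1
    else:
        ga_z = rng.standard_normal()
        ga = float(np.clip(28.5 + 2.2 * ga_z, 23.0, 32.9))
        # correlated latent drives the ultrasound code: lower GA, worse grade
        r = abs(ga_us_rank_corr)
        z = ga_us_rank_corr * ga_z + np.sqrt(1 - r**2) * rng.standard_normal()
        us = int(np.digitize(z, [0.4, 1.2]))
    m = ef_model
    ef = (
        m["b0"]
        + m["b_coupling"] * coupling_scale
        + m["b_ga"] * ga
        + m["b_interaction"] * coupling_scale * (ga - 35.0)
        + rng.normal(0.0, m["noise_sd"])
    )
    return {"ga_weeks": round(ga, 1), "us_code": us, "ef_score": round(float(ef), 2)}


# ---------------------------------------------------------------------------
# realignment and spatial-map fixtures
# ---------------------------------------------------------------------------

def generate_realignment(
    T: int,
    drift_scale: float = 0.02,
    spikes: Sequence[tuple[int, Sequence[float], Sequence[float]]] = (),
    seed: int | None = None,
    rotation_scale_ratio: float = 0.01,
) -> np.ndarray:
    """Synthetic (T, 6) realignment series: smooth drift plus injected spikes.

    Columns are x, y, z translations (mm) then rotations about x, y, z
    (radians).  Drift is a boxcar-smoothed Gaussian random walk whose
    per-step translation scale is ``drift_scale`` mm (rotations scaled by
    ``rotation_scale_ratio``).  Each spike ``(index, d_mm, d_rad)`` adds a
    transient single-volume excursion at that index.
    """
    for idx, *_ in spikes:
        if not (1 <= idx <= T - 1):
            raise ValueError(f"spike index {idx} outside [1, T-1]")
    rng = np.random.default_rng(seed)
    scales = np.array([drift_scale] * 3 + [drift_scale * rotation_scale_ratio] * 3)
    steps = rng.standard_normal((T, 6)) * scales
    walk = np.cumsum(steps, axis=0)
    if T >= 5:  # boxcar smoothing keeps the drift slow and realistic
        kernel = np.ones(5) / 5.0
        walk = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, walk)
    walk -= walk[0]
    for idx, d_mm, d_rad in spikes:
        walk[idx, :3] += np.asarray(d_mm, dtype=float)
        walk[idx, 3:] += np.asarray(d_rad, dtype=float)
    return walk


def generate_component_maps(
    templates: Sequence[np.ndarray],
    snr: float,
    seed: int | None = None,
    n_distractors: int = 4,
) -> np.ndarray:
    """One noisy spatial map per template plus pure-noise distractor maps.

    Each template's binary indicator is scaled by ``snr`` and unit Gaussian
    voxel noise added; distractors are pure noise.  Returns a stack of
    shape (n_templates + n_distractors, *grid).
    """
    grids = {np.asarray(t).shape for t in templates}
    if len(grids) != 1:
        raise ValueError("templates must share a voxel grid")
    grid = grids.pop()
    rng = np.random.default_rng(seed)
    maps = []
    for t in templates:
        maps.append(snr * np.asarray(t, dtype=float) + rng.standard_normal(grid))
    for _ in range(n_distractors):
        maps.append(rng.standard_normal(grid))
    return np.stack(maps)


# ---------------------------------------------------------------------------
# cohort I/O: TSV time courses + JSON-lines manifest
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, out_dir: str | Path, network_names: Sequence[str] | None = None) -> Path:
    """Write per-subject TSV time courses, realignment text files and a
    JSON-lines manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = cohort.subjects[0].timecourses.shape[0]
    names = list(network_names) if network_names else [f"net{i}" for i in range(k)]
    manifest = out / "cohort_manifest.jsonl"
    with manifest.open("w") as fh:
        for s in cohort.subjects:
            tc_path = out / f"{s.subject_id}_timecourses.tsv"
            pd.DataFrame(s.timecourses.T, columns=names).to_csv(
                tc_path, sep="\t", index=False, float_format="%.6f"
            )
            rp_path = out / f"rp_{s.subject_id}.txt"
            np.savetxt(rp_path, s.realignment, fmt="%.6e")
            fh.write(
                json.dumps(
                    {
                        "subject_id": s.subject_id,
                        "group": s.group,
                        "timecourses": tc_path.name,
                        "realignment": rp_path.name,
                        "sampling_interval": cohort.sampling_interval,
                        "covariates": s.covariates,
                    }
                )
                + "\n"
            )
    return manifest


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Read a cohort back from a JSON-lines manifest written by save_cohort."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    subjects = []
    sampling = 2.0
    with manifest_path.open() as fh:
        for line in fh:
            rec = json.loads(line)
            tc = pd.read_csv(base / rec["timecourses"], sep="\t").to_numpy().T
            rp = np.loadtxt(base / rec["realignment"])
            sampling = float(rec.get("sampling_interval", 2.0))
            subjects.append(
                Subject(
                    subject_id=rec["subject_id"],
                    group=rec["group"],
                    timecourses=tc,
                    realignment=rp,
                    covariates=rec.get("covariates", {}),
                )
            )
    return Cohort(subjects=tuple(subjects), sampling_interval=sampling)
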