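"""Synthetic multi-site lifespan cohorts for exercising the brain-age pipeline.

Real resting-state cohorts suitable for brain-age modelling are access
restricted, so this module generates datasets with the same statistical
skeleton: a lifespan age distribution spread over several acquisition
sites, parcel-level BOLD-like time series whose modular correlation
structure drifts with age (within-module coupling weakens, between-module
coupling strengthens), motion spikes that produce censorable frames, an
additive per-site offset and a per-subject global offset on Fisher-z
connectivity, and an optional "carrier" group whose *effective* brain age
is shifted by a configurable number of years while chronological age is
left untouched.  Every downstream stage (scrubbing, mean regression, graph
metrics, ranking, network selection, PAD inference) can therefore be
tested against planted ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "build_target_covariance",
    "sample_timeseries",
    "generate_cohort",
]

#: columns of participants.tsv, in order
PARTICIPANT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "site",
    "group",
    "amyloid_load",
    "amyloid_positive",
    "parental_onset_age",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Correlation drift is linear in (effective) age: within-module
    correlations start at ``within_module_r0`` and change by
    ``within_slope`` per year (negative — coupling weakens), between-module
    correlations start at ``between_module_r0`` and change by
    ``between_slope`` per year (positive).  All correlation targets are
    projected to the nearest positive semidefinite matrix before sampling.
    """

    n_subjects_per_group: int | tuple[int, ...] = 30
    groups: tuple[tuple[str, float], ...] = (("control", 0.0), ("carrier", 8.0))
    age_range: tuple[float, float] = (18.0, 90.0)
    n_regions: int = 60
    n_modules: int = 5
    T_frames: int = 300
    tr_seconds: float = 2.0
    within_module_r0: float = 0.45
    within_slope: float = -0.002
    between_module_r0: float = 0.05
    between_slope: float = 0.001
    site_labels: tuple[str, ...] = ("siteA", "siteB")
    site_offset_sd: float = 0.02
    global_offset_sd: float = 0.05
    spike_prob: float = 0.02
    fd_baseline_mm: float = 0.15
    fd_spike_mm: float = 0.8
    subject_noise_sd: float = 0.18
    edge_baseline_jitter_sd: float = 0.05
    edge_slope_jitter_sd: float = 0.002
    region_aging_sd: float = 0.003
    dispersion_slope: float = -0.012
    age_jitter_sd: float = 2.0
    amyloid_noise_sd: float = 0.08
    group_age_ranges: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not (0 <= lo < hi <= 120):
            raise ValueError("age_range must satisfy 0 <= min < max <= 120")
        if self.within_module_r0 <= self.between_module_r0:
            raise ValueError(
                "within_module_r0 must exceed between_module_r0 at the "
                "minimum age"
            )
        if self.n_modules < 1 or self.n_regions < self.n_modules:
            raise ValueError("need at least one region per module")
        if isinstance(self.n_subjects_per_group, (tuple, list)) and len(
            self.n_subjects_per_group
        ) != len(self.groups):
            raise ValueError("per-group sizes must match number of groups")
        if self.group_age_ranges is not None and len(self.group_age_ranges) != len(
            self.groups
        ):
            raise ValueError("per-group age ranges must match number of groups")
        # reject specs whose linear drift leaves (-1, 1) anywhere in range
        for age in self.age_range:
            for r in (
                self.within_module_r0 + self.within_slope * age,
                self.between_module_r0 + self.between_slope * age,
            ):
                if abs(r) >= 1:
                    raise ValueError(
                        f"correlation target |r|={abs(r):.3f} >= 1 at age "
                        f"{age}; rescale slopes/intercepts"
                    )

    def module_assignment(self) -> np.ndarray:
        """Region -> module labels, modules as equal as possible."""
        return np.array_split(np.arange(self.n_regions), self.n_modules)

    def group_sizes(self) -> list[int]:
        if isinstance(self.n_subjects_per_group, (tuple, list)):
            return list(self.n_subjects_per_group)
        return [self.n_subjects_per_group] * len(self.groups)


@dataclass
class SubjectRecord:
    """One synthetic participant.

    ``effective_age`` (chronological + group delta + individual jitter)
    drives the generated connectivity; ``chronological_age`` is what the
    pipeline sees.  With zero delta and zero jitter the two coincide.
    """

    subject_id: str
    chronological_age: float
    effective_age: float
    group_label: str
    site: str
    amyloid_load: float | None = None
    amyloid_positive: bool | None = None
    parental_onset_age: float | None = None


def _nearest_psd(mat: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clip to PSD, then renormalize the diagonal to 1."""
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, eig_floor, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def build_target_covariance(effective_age: float, spec: CohortSpec) -> np.ndarray:
    """Block-structured correlation target at a given effective age.

    Within-module entries are ``within_module_r0 + within_slope * age``,
    between-module entries ``between_module_r0 + between_slope * age``;
    the raw block matrix is projected to the nearest positive semidefinite
    correlation matrix (eigenvalue clipping, diagonal renormalized).
    """
    if not (0.0 <= effective_age <= 120.0):
        raise ValueError(f"effective_age {effective_age} outside [0, 120]")
    r_w = spec.within_module_r0 + spec.within_slope * effective_age
    r_b = spec.between_module_r0 + spec.between_slope * effective_age
    if abs(r_w) >= 1 or abs(r_b) >= 1:
        raise ValueError("correlation target outside (-1, 1); reject spec")
    n = spec.n_regions
    target = np.full((n, n), r_b)
    for idx in spec.module_assignment():
        target[np.ix_(idx, idx)] = r_w
    np.fill_diagonal(target, 1.0)
    return _nearest_psd(target)


def _perturb_correlation(
    target: np.ndarray, z_offset: np.ndarray
) -> np.ndarray:
    """Add a Fisher-z offset to every off-diagonal entry, back-transform,
    and re-project to PSD."""
    z = np.arctanh(np.clip(target, -1 + 1e-7, 1 - 1e-7))
    np.fill_diagonal(z, 0.0)
    z = z + z_offset
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    return _nearest_psd(r)


def _symmetric_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    m = rng.normal(0.0, sd, size=(n, n))
    m = (m + m.T) / np.sqrt(2.0)
    np.fill_diagonal(m, 0.0)
    return m


def sample_timeseries(
    target_cov: np.ndarray,
    spec: CohortSpec,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a (T_frames, n_regions) Gaussian series plus an FD trace.

    Frames flagged as motion spikes (probability ``spike_prob``) get
    additive high-variance noise and FD equal to ``fd_spike_mm``; clean
    frames get FD ~ |Normal(fd_baseline_mm, 0.05)|.
    """
    n = target_cov.shape[0]
    if spec.T_frames < n + 10:
        import warnings

        warnings.warn(
            f"T_frames={spec.T_frames} < n_regions+10={n + 10}: sample "
            "correlations will be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    w, v = np.linalg.eigh((target_cov + target_cov.T) / 2.0)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    data = rng.standard_normal((spec.T_frames, n)) @ factor.T

    spikes = rng.random(spec.T_frames) < spec.spike_prob
    fd = np.abs(rng.normal(spec.fd_baseline_mm, 0.05, size=spec.T_frames))
    if spikes.any():
        data[spikes] += rng.normal(0.0, 3.0, size=(int(spikes.sum()), n))
        fd[spikes] = spec.fd_spike_mm
    return data, fd


def _edge_fields(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Cohort-fixed per-edge Fisher-z baseline offsets and aging-rate jitter.

    Real connectomes age heterogeneously: individual connections have their
    own baselines and their own aging rates around the module-level trend.
    Without this spread, every edge of a mean-regressed matrix would cross
    zero at the same (mid-cohort) age and metrics of the residual matrix
    would alias young against old subjects.  Both fields are deterministic
    functions of the cohort seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 22801763]))
    baseline = _symmetric_noise(rng, spec.n_regions, spec.edge_baseline_jitter_sd)
    slope = _symmetric_noise(rng, spec.n_regions, spec.edge_slope_jitter_sd)
    # region-level aging rates: an edge's drift inherits the mean of its
    # endpoints' rates, so fast-aging "hub" regions reorganize the degree
    # and strength structure that the global metrics summarize
    rho = rng.normal(0.0, spec.region_aging_sd, size=spec.n_regions)
    slope = slope + (rho[:, None] + rho[None, :]) / 2.0
    np.fill_diagonal(slope, 0.0)
    return baseline, slope


def _site_offsets(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Per-site additive Fisher-z edge offsets, fixed by the cohort seed."""
    out = {}
    for k, site in enumerate(spec.site_labels):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919, k]))
        out[site] = _symmetric_noise(rng, spec.n_regions, spec.site_offset_sd)
    return out


def make_subjects(spec: CohortSpec) -> list[SubjectRecord]:
    """Sample the participants table (ages, sites, group deltas, amyloid)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 104729]))
    records: list[SubjectRecord] = []
    counter = 0
    ranges = spec.group_age_ranges or tuple(spec.age_range for _ in spec.groups)
    for (label, delta), n_group, (lo, hi) in zip(
        spec.groups, spec.group_sizes(), ranges
    ):
        for i in range(n_group):
            age = rng.uniform(lo, hi)
            jitter = rng.normal(0.0, spec.age_jitter_sd)
            eff = float(np.clip(age + delta + jitter, 0.0, 120.0))
            site = spec.site_labels[counter % len(spec.site_labels)]
            # amyloid burden tracks the planted brain-age offset plus noise,
            # so PAD-vs-amyloid partial correlations have recoverable signal
            load = float(
                1.2
                + 0.03 * (eff - age)
                + rng.normal(0.0, spec.amyloid_noise_sd)
            )
            onset: float | None = None
            if delta != 0.0:
                onset = float(age + rng.normal(10.0, 5.0))
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{counter:04d}",
                    chronological_age=float(age),
                    effective_age=eff,
                    group_label=label,
                    site=site,
                    amyloid_load=load,
                    amyloid_positive=bool(load >= 1.31),
                    parental_onset_age=onset,
                )
            )
            counter += 1
    return records


def subject_timeseries(
    record: SubjectRecord,
    spec: CohortSpec,
    site_offsets: dict[str, np.ndarray] | None = None,
    index: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one subject's time series + FD trace.

    The correlation target at the subject's effective age is perturbed in
    Fisher-z space by the site offset, a per-subject global offset
    (mimicking residual motion load — what mean-regression denoising is
    meant to remove) and per-edge subject noise, then sampled.
    """
    if site_offsets is None:
        site_offsets = _site_offsets(spec)
    idx = index if index is not None else int(record.subject_id.split("-")[-1])
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 15485863, idx]))
    target = build_target_covariance(record.effective_age, spec)
    baseline_jit, slope_jit = _edge_fields(spec)
    pivot = sum(spec.age_range) / 2.0
    d_age = record.effective_age - pivot
    # the amplitude of the subject's idiosyncratic connectivity pattern
    # shrinks with age (functional dedifferentiation): because that field
    # is random per subject, its per-edge mean is zero and the amplitude
    # change survives mean-regression denoising, giving magnitude-based
    # global metrics a monotone aging signal
    amplitude = max(0.1, 1.0 + spec.dispersion_slope * d_age)
    z_offset = site_offsets[record.site].copy()
    z_offset += baseline_jit + slope_jit * d_age
    z_offset += _symmetric_noise(rng, spec.n_regions, spec.subject_noise_sd * amplitude)
    z_offset += float(rng.normal(0.0, spec.global_offset_sd))
    np.fill_diagonal(z_offset, 0.0)
    perturbed = _perturb_correlation(target, z_offset)
    ts_seed = int(rng.integers(0, 2**31 - 1))
    return sample_timeseries(perturbed, spec, ts_seed)


def _fmt(x: float | bool | None) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "1" if x else "0"
    return f"{x:.6g}"


def participants_frame(records: list[SubjectRecord], spec: CohortSpec) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 32452843]))
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "age": f"{r.chronological_age:.4f}",
                "sex": "F" if rng.random() < 0.5 else "M",
                "site": r.site,
                "group": r.group_label,
                "amyloid_load": _fmt(r.amyloid_load),
                "amyloid_positive": _fmt(r.amyloid_positive),
                "parental_onset_age": _fmt(r.parental_onset_age),
            }
        )
    return pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)


def generate_cohort(spec: CohortSpec, out_dir: str | Path, overwrite: bool = False) -> Path:
    """Write a full synthetic dataset to ``out_dir``.

    Layout: ``participants.tsv``, one ``<id>_timeseries.tsv`` (frames x
    regions, region-label header) and one ``<id>_fd.tsv`` per subject, and
    ``manifest.json`` echoing the spec and seed.  Refuses to write into an
    existing non-empty directory unless ``overwrite`` is set.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is non-empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    records = make_subjects(spec)
    table = participants_frame(records, spec)
    table.to_csv(out / "participants.tsv", sep="\t", index=False)

    offsets = _site_offsets(spec)
    labels = [f"R{i:03d}" for i in range(spec.n_regions)]
    files = ["participants.tsv"]
    for i, rec in enumerate(records):
        data, fd = subject_timeseries(rec, spec, offsets, index=i)
        ts_path = out / f"{rec.subject_id}_timeseries.tsv"
        fd_path = out / f"{rec.subject_id}_fd.tsv"
        pd.DataFrame(data, columns=labels).to_csv(
            ts_path, sep="\t", index=False, float_format="%.6f"
        )
        pd.DataFrame({"fd_mm": fd}).to_csv(
            fd_path, sep="\t", index=False, float_format="%.6f"
        )
        files += [ts_path.name, fd_path.name]

    manifest = {
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(spec).items()
        },
        "seed": spec.seed,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
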