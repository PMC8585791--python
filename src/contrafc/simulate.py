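"""Synthetic resting-state BOLD cohorts with planted network disruption.

The generator emulates the statistical structure the analysis assumes: ROI
time series drawn from a block-structured multivariate normal whose blocks
are the resting-state networks (mirrored across hemispheres), superimposed
on a large baseline intensity, with slow sinusoidal scanner drift shared
across ROIs and occasional whole-brain motion spikes.

Surgical disruption is planted directly in covariance space: for a network
with disruption delta in [0, 1], the post-operative correlation block is the
mixture (1 - delta) * pre-block + delta * (random correlation block), so the
ground-truth magnitude of network change is exactly parameterised and the
pipeline's job — recovering which group was perturbed less — has a known
answer.

Defaults reflect the acquisition this emulates: two 200-frame runs per scan
at TR 2.07 s, 150 ROIs per hemisphere with the canonical per-network ROI
counts (SDN 17, SLN 3, CON 8, AN 6, DMN 31, PMN 3, VN 19, FPN 15, SN 8,
VAN 5, DAN 7; the 28 remaining ROIs per hemisphere are unlabeled), and a
12 + 12 two-group cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .atlas import ANALYZED_NETWORKS, ROIRecord, ROITable
from .errors import ParameterError, ValidationError
from .preprocess import TimeSeriesRun, make_run

#: Canonical per-hemisphere ROI counts of the analyzed networks.
DEFAULT_NETWORK_SIZES: dict[str, int] = {
    "SDN": 17, "SLN": 3, "CON": 8, "AN": 6, "DMN": 31, "PMN": 3,
    "VN": 19, "FPN": 15, "SN": 8, "VAN": 5, "DAN": 7,
}

#: Networks carrying the planted disruption in the default cohort.
DEFAULT_DISRUPTED_NETWORKS: tuple[str, ...] = ("SDN", "FPN", "SN", "DAN")

_ABBR_TO_NAME = dict(ANALYZED_NETWORKS)


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for the synthetic cohort.

    rho_within / rho_between are the within-network and between-network
    correlations of the block model; baseline and noise_scale set the mean
    BOLD intensity and the fluctuation amplitude (arbitrary units);
    drift_amplitude and drift_freq_hz shape the shared slow drift; spikes
    offset whole frames by spike_magnitude times the run's grand RMS at
    rate spike_rate per frame.
    """

    n_per_hemisphere: int = 150
    network_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_SIZES)
    )
    rho_within: float = 0.5
    rho_between: float = 0.05
    n_frames: int = 200
    n_runs: int = 2
    tr_seconds: float = 2.07
    baseline: float = 100.0
    noise_scale: float = 0.2
    drift_amplitude: float = 1.0
    drift_freq_hz: float = 0.005
    spike_rate: float = 0.02
    spike_magnitude: float = 0.10

    def __post_init__(self) -> None:
        if self.n_per_hemisphere < 1:
            raise ParameterError("n_per_hemisphere must be >= 1")
        total = sum(self.network_sizes.values())
        if total > self.n_per_hemisphere:
            raise ParameterError(
                f"network sizes sum to {total} > n_per_hemisphere "
                f"{self.n_per_hemisphere}"
            )
        unknown = set(self.network_sizes) - set(_ABBR_TO_NAME)
        if unknown:
            raise ParameterError(f"unknown network(s) in network_sizes: {sorted(unknown)}")
        if not -1 < self.rho_between <= self.rho_within < 1:
            raise ParameterError(
                "need -1 < rho_between <= rho_within < 1, got "
                f"rho_within={self.rho_within}, rho_between={self.rho_between}"
            )
        if self.n_frames < 2 or self.n_runs < 1:
            raise ParameterError("n_frames must be >= 2 and n_runs >= 1")
        if self.tr_seconds <= 0:
            raise ParameterError("tr_seconds must be > 0")
        if not 0 <= self.spike_rate < 1:
            raise ParameterError("spike_rate must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticSubject:
    """One simulated patient: pre/post runs plus the planted ground truth."""

    subject_id: str
    group: str
    lesion_side: str
    pre_runs: tuple[TimeSeriesRun, ...]
    post_runs: tuple[TimeSeriesRun, ...]
    ground_truth_delta: dict[str, float]


@dataclass(frozen=True)
class GroupSpec:
    """Size and per-network disruption of one surgery group."""

    name: str
    n_subjects: int
    delta: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("group size must be >= 1")
        for network, d in self.delta.items():
            if not 0 <= d <= 1:
                raise ParameterError(
                    f"group {self.name!r}: delta for {network} must be in "
                    f"[0, 1], got {d}"
                )


def default_group_specs(delta_a: float = 0.6, delta_b: float = 0.2,
                        n_per_group: int = 12,
                        networks: Sequence[str] = DEFAULT_DISRUPTED_NETWORKS,
                        ) -> tuple[GroupSpec, GroupSpec]:
    """The default 12 + 12 cohort: open surgery disrupts the targeted
    networks more (delta 0.6) than the minimally invasive group (0.2)."""
    return (
        GroupSpec("craniotomy", n_per_group, {n: delta_a for n in networks}),
        GroupSpec("LITT", n_per_group, {n: delta_b for n in networks}),
    )


@dataclass(frozen=True)
class Cohort:
    """A simulated cohort plus the atlas and covariance scaffolding."""

    table: ROITable
    subjects: tuple[SyntheticSubject, ...]
    params: SimulationParams
    seed: int


def _hemisphere_labels(params: SimulationParams) -> list[str]:
    """Per-hemisphere label sequence: analyzed networks in canonical order,
    then unlabeled filler."""
    labels: list[str] = []
    for abbr, name in ANALYZED_NETWORKS:
        labels.extend([name] * int(params.network_sizes.get(abbr, 0)))
    labels.extend(["Unlabeled"] * (params.n_per_hemisphere - len(labels)))
    return labels


def make_block_covariance(params: SimulationParams) -> tuple[np.ndarray, ROITable]:
    """Block correlation matrix over both hemispheres plus a matching atlas.

    Same-network ROI pairs (within or across hemispheres — networks are
    mirrored) correlate at rho_within; all other pairs, including unlabeled
    ROIs, at rho_between; diagonal is 1.  The result is checked for positive
    semidefiniteness.
    """
    labels_hemi = _hemisphere_labels(params)
    n_hemi = params.n_per_hemisphere
    labels = labels_hemi + labels_hemi
    n = 2 * n_hemi

    records = []
    for i, label in enumerate(labels):
        left = i < n_hemi
        k = i if left else i - n_hemi
        frac = k / max(n_hemi - 1, 1)
        records.append(
            ROIRecord(
                roi_id=f"{'L' if left else 'R'}{k + 1:03d}",
                x=(-1.0 if left else 1.0) * (15.0 + 55.0 * frac),
                y=-95.0 + 160.0 * ((k * 37) % n_hemi) / n_hemi,
                z=-45.0 + 100.0 * ((k * 53) % n_hemi) / n_hemi,
                network=label,
            )
        )
    table = ROITable(records=tuple(records), provenance="synthetic block model")

    named = set(_ABBR_TO_NAME.values())
    sigma = np.full((n, n), params.rho_between)
    for name in named:
        idx = np.flatnonzero(np.array(labels) == name)
        if idx.size:
            sigma[np.ix_(idx, idx)] = params.rho_within
    np.fill_diagonal(sigma, 1.0)

    smallest = float(np.linalg.eigvalsh(sigma)[0])
    if smallest < -1e-8:
        raise ParameterError(
            f"block covariance is not positive semidefinite "
            f"(smallest eigenvalue {smallest:.3e})"
        )
    return sigma, table


def network_blocks(table: ROITable) -> dict[str, np.ndarray]:
    """Canonical-order index arrays of each analyzed network (both hemispheres)."""
    labels = np.array(table.networks)
    blocks = {}
    for abbr, name in ANALYZED_NETWORKS:
        idx = np.flatnonzero(labels == name)
        if idx.size:
            blocks[abbr] = idx
    return blocks


def random_correlation_block(k: int, rng: np.random.Generator) -> np.ndarray:
    """Random k x k correlation matrix (normalised Wishart, k + 2 df)."""
    w = rng.standard_normal((k, k + 2))
    s = w @ w.T
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)


def perturb_covariance(
    sigma: np.ndarray,
    blocks: Mapping[str, np.ndarray],
    delta: Mapping[str, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Mix targeted network blocks toward random correlation structure.

    For each network with disruption ``d``, the principal block over that
    network's ROIs (both hemispheres) becomes
    ``(1 - d) * block + d * random_correlation_block``.  Off-block entries
    are untouched.  If mixing breaks positive semidefiniteness the matrix is
    projected to the nearest correlation-normalised PSD matrix; the second
    return value flags that projection.
    """
    out = np.array(sigma, dtype=float, copy=True)
    changed = False
    for network, d in delta.items():
        if network not in blocks:
            raise ValidationError(f"unknown network {network!r} in delta map")
        if not 0 <= d <= 1:
            raise ValidationError(f"delta for {network} must be in [0, 1], got {d}")
        idx = blocks[network]
        # always consume randomness so the stream is delta-independent
        resampled = random_correlation_block(idx.size, rng)
        if d == 0:
            continue
        block = out[np.ix_(idx, idx)]
        out[np.ix_(idx, idx)] = (1.0 - d) * block + d * resampled
        changed = True
    projected = False
    if changed:
        # cheap PSD check first; eigendecompose only when projection is needed
        try:
            np.linalg.cholesky(out + 1e-10 * np.eye(out.shape[0]))
        except np.linalg.LinAlgError:
            eigvals, eigvecs = np.linalg.eigh(out)
            if eigvals[0] < -1e-10:
                clipped = np.clip(eigvals, 0.0, None)
                out = (eigvecs * clipped) @ eigvecs.T
                d_ = np.sqrt(np.clip(np.diag(out), 1e-12, None))
                out = out / np.outer(d_, d_)
                out = (out + out.T) / 2.0
                np.fill_diagonal(out, 1.0)
                projected = True
    return out, projected


def _matrix_sqrt(sigma: np.ndarray) -> np.ndarray:
    """Lower-triangular / symmetric square root tolerant of semidefiniteness."""
    try:
        return np.linalg.cholesky(sigma + 1e-12 * np.eye(sigma.shape[0]))
    except np.linalg.LinAlgError:
        eigvals, eigvecs = np.linalg.eigh(sigma)
        if eigvals[0] < -1e-8:
            raise ParameterError(
                f"covariance is not positive semidefinite "
                f"(smallest eigenvalue {eigvals[0]:.3e})"
            ) from None
        return eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))


def simulate_run(
    sigma: np.ndarray,
    params: SimulationParams,
    seed,
    run_id: str = "",
    root: np.ndarray | None = None,
) -> TimeSeriesRun:
    """One synthetic BOLD run: correlated noise + baseline + drift + spikes.

    Frames are i.i.d. draws from N(0, sigma) scaled by ``noise_scale`` and
    offset by ``baseline``; a shared sinusoid at ``drift_freq_hz`` emulates
    slow scanner drift; spike frames (rate ``spike_rate``) are offset on all
    ROIs by ``spike_magnitude`` times the run's grand RMS intensity.
    Fully deterministic given the seed.  ``root`` may carry a precomputed
    matrix square root of ``sigma`` (reused across a subject's runs).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if root is None:
        root = _matrix_sqrt(np.asarray(sigma, dtype=float))
    n = root.shape[0]
    noise = rng.standard_normal((params.n_frames, n)) @ root.T
    data = params.baseline + params.noise_scale * noise

    t = np.arange(params.n_frames) * params.tr_seconds
    phase = rng.uniform(0.0, 2.0 * np.pi)
    data = data + (
        params.drift_amplitude
        * np.sin(2.0 * np.pi * params.drift_freq_hz * t + phase)[:, None]
    )

    spike_frames = np.flatnonzero(rng.random(params.n_frames) < params.spike_rate)
    if spike_frames.size:
        grand_rms = float(np.sqrt(np.mean(data**2)))
        data[spike_frames] += params.spike_magnitude * grand_rms
    return make_run(data, tr_seconds=params.tr_seconds, run_id=run_id)


def simulate_subject(
    subject_id: str,
    group: str,
    lesion_side: str,
    sigma: np.ndarray,
    blocks: Mapping[str, np.ndarray],
    delta: Mapping[str, float],
    params: SimulationParams,
    rng: np.random.Generator,
    pre_root: np.ndarray | None = None,
) -> SyntheticSubject:
    """Pre runs from the base covariance, post runs from its perturbation."""
    if pre_root is None:
        pre_root = _matrix_sqrt(np.asarray(sigma, dtype=float))
    pre_runs = tuple(
        simulate_run(sigma, params, rng, run_id=f"{subject_id}_pre_r{k + 1}",
                     root=pre_root)
        for k in range(params.n_runs)
    )
    post_sigma, _ = perturb_covariance(sigma, blocks, delta, rng)
    post_root = _matrix_sqrt(post_sigma)
    post_runs = tuple(
        simulate_run(post_sigma, params, rng,
                     run_id=f"{subject_id}_post_r{k + 1}", root=post_root)
        for k in range(params.n_runs)
    )
    return SyntheticSubject(
        subject_id=subject_id,
        group=group,
        lesion_side=lesion_side,
        pre_runs=pre_runs,
        post_runs=post_runs,
        ground_truth_delta=dict(delta),
    )


def simulate_cohort(
    group_specs: Sequence[GroupSpec] | None = None,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> Cohort:
    """Simulate a full two-group cohort (defaults: 12 + 12 subjects).

    All subjects share the pre-operative block covariance; each subject's
    post covariance carries that subject's own random perturbation of the
    group's delta map.  Lesion sides are drawn uniformly.
    """
    params = params or SimulationParams()
    specs = tuple(group_specs) if group_specs else default_group_specs()
    if len({s.name for s in specs}) != len(specs):
        raise ValidationError("group names must be unique")
    rng = np.random.default_rng(seed)
    sigma, table = make_block_covariance(params)
    blocks = network_blocks(table)
    pre_root = _matrix_sqrt(sigma)
    subjects = []
    for spec in specs:
        for i in range(spec.n_subjects):
            subject_id = f"{spec.name}_{i + 1:02d}"
            lesion_side = "L" if rng.random() < 0.5 else "R"
            subjects.append(
                simulate_subject(
                    subject_id, spec.name, lesion_side, sigma, blocks,
                    dict(spec.delta), params, rng, pre_root=pre_root,
                )
            )
    return Cohort(table=table, subjects=tuple(subjects), params=params,
                  seed=int(seed))


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write a cohort in the pipeline's on-disk formats.

    Produces ``roi_table.tsv``, one time-series TSV per run under ``runs/``,
    a JSON ``manifest.json`` (with synthetic scan dates), and the planted
    ``ground_truth.json``.  Returns the manifest path.
    """
    from .connectivity import write_timeseries_tsv

    outdir = Path(outdir)
    (outdir / "runs").mkdir(parents=True, exist_ok=True)
    cohort.table.write_tsv(outdir / "roi_table.tsv")

    manifest = []
    truth = {}
    for j, subject in enumerate(cohort.subjects):
        truth[subject.subject_id] = subject.ground_truth_delta
        entry = {
            "subject_id": subject.subject_id,
            "group": subject.group,
            "lesion_side": subject.lesion_side,
            "pre": {"scan_id": f"{subject.subject_id}_pre",
                    "date": "2016-01-01", "runs": []},
            "post": [{"scan_id": f"{subject.subject_id}_post",
                      "date": f"2016-{7 + j % 6:02d}-15", "runs": []}],
        }
        for run in subject.pre_runs:
            path = outdir / "runs" / f"{run.run_id}.tsv"
            write_timeseries_tsv(run, cohort.table.roi_ids, path)
            entry["pre"]["runs"].append(str(path.relative_to(outdir)))
        for run in subject.post_runs:
            path = outdir / "runs" / f"{run.run_id}.tsv"
            write_timeseries_tsv(run, cohort.table.roi_ids, path)
            entry["post"][0]["runs"].append(str(path.relative_to(outdir)))
        manifest.append(entry)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(
            {"tr_seconds": cohort.params.tr_seconds, "seed": cohort.seed,
             "subjects": manifest},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path
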