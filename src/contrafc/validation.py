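"""Repeat-simulation validation studies.

These procedures characterise the statistical behaviour of the full
pipeline on synthetic cohorts: type-I error calibration of the one-tailed
Welch comparison under a true null, power to recover a planted group
difference in network disruption, and monotonicity of the pre/post
similarity coefficient in the disruption magnitude.  They are used by the
test suite and by the reproduction script; every replicate is seeded
deterministically from a single base seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .atlas import contralesional_indices
from .compare import HEMISPHERE, build_partition
from .pipeline import PipelineConfig, analyze_subject, run_cohort
from .simulate import (DEFAULT_DISRUPTED_NETWORKS, GroupSpec,
                       SimulationParams, make_block_covariance,
                       network_blocks, simulate_cohort, simulate_subject)

_MOD = 2**31 - 1


def _replicate_seed(seed: int, rep: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    return (int(seed) * 1_000_003 + 7919 * rep + 1) % _MOD


def _hemisphere_row(results) -> dict:
    row = results.loc[results["network"] == HEMISPHERE].iloc[0]
    return {"p": float(row["p"]),
            "G_a": float(row["G_craniotomy"]),
            "G_b": float(row["G_LITT"])}


@dataclass(frozen=True)
class CalibrationResult:
    p_values: tuple[float, ...]
    alpha: float

    @property
    def type_one_rate(self) -> float:
        return float(np.mean(np.asarray(self.p_values) < self.alpha))


def type_one_error_study(
    n_replicates: int = 200,
    n_per_group: int = 12,
    delta: float = 0.4,
    seed: int = 0,
    alpha: float = 0.05,
    params: SimulationParams | None = None,
) -> CalibrationResult:
    """Hemisphere-level one-tailed Welch p under a true null.

    Both groups receive identical per-network disruption, so any detected
    difference is a false positive; across replicate cohorts the p-value
    should be uniform and the rejection rate at ``alpha`` close to alpha.
    """
    params = params or SimulationParams()
    specs = (
        GroupSpec("craniotomy", n_per_group,
                  {n: delta for n in DEFAULT_DISRUPTED_NETWORKS}),
        GroupSpec("LITT", n_per_group,
                  {n: delta for n in DEFAULT_DISRUPTED_NETWORKS}),
    )
    config = PipelineConfig()
    ps = []
    for rep in range(n_replicates):
        cohort = simulate_cohort(specs, params, seed=_replicate_seed(seed, rep))
        ps.append(_hemisphere_row(run_cohort(cohort, config).results)["p"])
    return CalibrationResult(p_values=tuple(ps), alpha=alpha)


@dataclass(frozen=True)
class PowerResult:
    n_replicates: int
    n_detected: int
    n_correct_direction: int

    @property
    def power(self) -> float:
        return self.n_detected / self.n_replicates


def recovery_power_study(
    n_replicates: int = 100,
    delta_a: float = 0.6,
    delta_b: float = 0.2,
    n_per_group: int = 12,
    frames_per_scan: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PowerResult:
    """Recovery of a planted group difference in network disruption.

    Group A's targeted networks are disrupted at ``delta_a``, group B's at
    ``delta_b`` < ``delta_a``; a replicate counts as detected when the
    hemisphere-level one-tailed p is below ``alpha``, and as directionally
    correct when the less-disrupted group shows the higher group-wise mean.
    """
    params = SimulationParams(n_frames=frames_per_scan // 2, n_runs=2)
    specs = (
        GroupSpec("craniotomy", n_per_group,
                  {n: delta_a for n in DEFAULT_DISRUPTED_NETWORKS}),
        GroupSpec("LITT", n_per_group,
                  {n: delta_b for n in DEFAULT_DISRUPTED_NETWORKS}),
    )
    config = PipelineConfig()
    detected = correct = 0
    for rep in range(n_replicates):
        cohort = simulate_cohort(specs, params, seed=_replicate_seed(seed, rep))
        row = _hemisphere_row(run_cohort(cohort, config).results)
        if row["G_b"] > row["G_a"]:
            correct += 1
            if row["p"] < alpha:
                detected += 1
    return PowerResult(n_replicates=n_replicates, n_detected=detected,
                       n_correct_direction=correct)


def delta_monotonicity_study(
    deltas: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_subjects: int = 50,
    seed: int = 0,
    params: SimulationParams | None = None,
) -> dict[float, float]:
    """Mean hemisphere-level pre/post similarity per disruption level.

    All analyzed networks are disrupted at the same delta; subjects are
    re-seeded identically across levels so the curves differ only through
    the perturbation.  Returns ``{delta: mean c}``.
    """
    params = params or SimulationParams()
    sigma, table = make_block_covariance(params)
    blocks = network_blocks(table)
    idx = contralesional_indices(table, "R")
    partition = build_partition(table, idx)
    config = PipelineConfig()
    out: dict[float, float] = {}
    for delta in deltas:
        rng = np.random.default_rng(_replicate_seed(seed, 0))
        cs = []
        for i in range(n_subjects):
            subject = simulate_subject(
                f"s{i}", "g", "R", sigma, blocks,
                {n: float(delta) for n in blocks}, params, rng,
            )
            scores, log = analyze_subject(
                subject.subject_id, subject.lesion_side,
                subject.pre_runs, subject.post_runs, table, config,
            )
            if not log.included:  # pragma: no cover - QC exclusion is rare here
                continue
            cs.append(next(s.c for s in scores if s.network == HEMISPHERE))
        out[float(delta)] = float(np.mean(cs))
    return out


def filter_contract_check(
    tr_seconds: float = 2.07,
    n_frames: int = 400,
) -> dict[str, float]:
    """RMS transmission of the default low-pass at a stop-band (0.2 Hz) and
    a pass-band (0.01 Hz) sinusoid."""
    from .preprocess import PreprocessParams, lowpass_filter, make_run

    params = PreprocessParams()
    t = np.arange(n_frames) * tr_seconds
    out = {}
    for label, freq in (("stopband_0.2hz", 0.2), ("passband_0.01hz", 0.01)):
        x = np.sin(2 * np.pi * freq * t)[:, None]
        run = make_run(np.tile(x, (1, 3)), tr_seconds=tr_seconds)
        y = lowpass_filter(run, params)
        out[label] = float(
            np.sqrt((y.data**2).mean()) / np.sqrt((x**2).mean())
        )
    return out
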