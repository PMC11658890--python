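"""Synthetic data generators for the depletion and kinetics assays.

Two experiment families are emulated:

* a randomized-PAM library depletion experiment — reads are the 206-nt library
  fragment with the randomized tetramer drawn from the post-cleavage PAM
  distribution implied by a :class:`RecognitionModel`;
* exponential progress curves — cleaved-fraction time courses and
  2-aminopurine (2AP) fluorescence traces with Gaussian noise.

All randomness is driven by integer seeds; a fixed seed reproduces
byte-identical FASTQ output and identical time courses.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .kinetics import TimeCourse
from .library import AmpliconDesign, DNA_ALPHABET, IUPAC_TO_BASES, default_design, matches_iupac

SampleRole = Literal["untreated", "non_targeting", "targeting"]
VALID_ROLES = ("untreated", "non_targeting", "targeting")


@dataclass(frozen=True)
class RecognitionModel:
    """Ordered IUPAC-rule model of PAM recognition.

    Each rule is an ``(iupac_pattern, cleavage_probability)`` pair over the
    randomized positions; the first matching rule wins.  PAMs matching no rule
    are cleaved with ``default_probability``.  Successful recognition depletes
    a PAM from the library, so the survival weight of PAM ``p`` in a targeting
    sample is ``1 - cleavage_probability(p)``.
    """

    rules: tuple[tuple[str, float], ...] = ()
    default_probability: float = 0.0
    randomized_length: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.default_probability <= 1.0:
            raise ValueError("default_probability must be in [0, 1]")
        for pattern, prob in self.rules:
            if len(pattern) != self.randomized_length:
                raise ValueError(
                    f"pattern {pattern!r} length != randomized_length "
                    f"{self.randomized_length}"
                )
            if not set(pattern.upper()) <= set(IUPAC_TO_BASES):
                raise ValueError(f"pattern {pattern!r} has non-IUPAC characters")
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"cleavage probability {prob} not in [0, 1]")

    def cleavage_probability(self, pam: str) -> float:
        for pattern, prob in self.rules:
            if matches_iupac(pattern, pam):
                return prob
        return self.default_probability

    def survival_weights(self, pams: Iterable[str]) -> pd.Series:
        """Per-PAM survival weight ``1 - cleavage_probability`` (targeting)."""
        return pd.Series(
            {p: 1.0 - self.cleavage_probability(p) for p in pams}, name="true_weight"
        )


@dataclass(frozen=True)
class SimulationPlan:
    """Full description of a simulated depletion experiment."""

    model: RecognitionModel
    reads_per_sample: int
    samples: tuple[tuple[str, SampleRole], ...]
    seed: int
    design: AmpliconDesign = field(default_factory=default_design)
    reverse_complement_fraction: float = 0.0
    substitution_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if not self.samples:
            raise ValueError("at least one sample required")
        for sample_id, role in self.samples:
            if role not in VALID_ROLES:
                raise ValueError(f"sample {sample_id!r}: unknown role {role!r}")
        if not 0.0 <= self.reverse_complement_fraction <= 1.0:
            raise ValueError("reverse_complement_fraction must be in [0, 1]")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")


@dataclass
class SimulatedSample:
    """Reads for one sample plus the generator's ground truth."""

    sample_id: str
    sample_role: SampleRole
    reads: list[str]  # sequences, post orientation/substitution
    true_pams: list[str]  # planted tetramer per read, library orientation
    ground_truth: pd.DataFrame  # pam, true_weight, expected_count


def _per_sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def simulate_pam_library_reads(plan: SimulationPlan) -> dict[str, SimulatedSample]:
    """Simulate per-sample reads from a randomized-PAM depletion experiment.

    The PAM of each read is multinomially sampled from a uniform prior over
    the ``4**L`` tetramers reweighted by survival: targeting samples use
    ``1 - cleavage_probability``, untreated and non-targeting samples survive
    uniformly.  Raises ``ValueError("library fully depleted")`` if the model
    cleaves every PAM with probability 1.
    """
    design = plan.design
    pams = design.library_spec().pams()
    n_pams = len(pams)
    targeting_weights = plan.model.survival_weights(pams)
    if (targeting_weights <= 0).all():
        raise ValueError("library fully depleted: every PAM is cleaved with probability 1")

    fragments = np.array([design.fragment(p) for p in pams])
    fragments_rc = np.array([reverse_complement(f) for f in fragments])

    out: dict[str, SimulatedSample] = {}
    for idx, (sample_id, role) in enumerate(plan.samples):
        rng = _per_sample_rng(plan.seed, idx)
        weights = (
            targeting_weights.to_numpy(dtype=float)
            if role == "targeting"
            else np.ones(n_pams)
        )
        probs = weights / weights.sum()
        counts = rng.multinomial(plan.reads_per_sample, probs)
        pam_idx = rng.permutation(np.repeat(np.arange(n_pams), counts))

        seqs = fragments[pam_idx]
        if plan.reverse_complement_fraction > 0:
            seqs = seqs.copy()
            flip = rng.random(len(pam_idx)) < plan.reverse_complement_fraction
            seqs[flip] = fragments_rc[pam_idx[flip]]
        if plan.substitution_rate > 0:
            reads = [_mutate(s, plan.substitution_rate, rng) for s in seqs]
        else:
            reads = seqs.tolist()

        truth = pd.DataFrame(
            {
                "pam": pams,
                "true_weight": weights / weights.sum(),
                "expected_count": plan.reads_per_sample * probs,
            }
        )
        out[sample_id] = SimulatedSample(
            sample_id=sample_id,
            sample_role=role,
            reads=reads,
            true_pams=np.asarray(pams)[pam_idx].tolist(),
            ground_truth=truth,
        )
    return out


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hit) == 0:
        return seq
    others = {b: [o.encode() for o in DNA_ALPHABET if o != b] for b in "ACGT"}
    for i in hit:
        arr[i] = others[arr[i].decode()][rng.integers(3)]
    return arr.tobytes().decode()


def write_fastq(sample: SimulatedSample, path: str | Path, quality_char: str = "I") -> Path:
    """Write a simulated sample as 4-line FASTQ (gzip if path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(sample.reads):
            fh.write(
                f"@{sample.sample_id}:{i} pam={sample.true_pams[i]}\n"
                f"{seq}\n+\n{quality_char * len(seq)}\n"
            )
    return path


def write_ground_truth(sample: SimulatedSample, path: str | Path) -> Path:
    path = Path(path)
    sample.ground_truth.to_csv(path, sep="\t", index=False)
    return path


def simulate_cleavage_timecourse(
    k: float,
    ymax: float,
    times: Iterable[float],
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int | None = None,
    condition: str = "simulated",
) -> TimeCourse:
    """Cleaved-fraction time course ``Y = Ymax*(1 - exp(-k*t))`` + noise.

    Values are clipped to [0, 1]; ``noise_sd = 0`` gives exact model values.
    ``k`` is per minute, ``times`` in minutes.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if k <= 0:
        raise ValueError("k must be positive")
    if not 0.0 <= ymax <= 1.0:
        raise ValueError("ymax must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        y = ymax * (1.0 - np.exp(-k * times))
        if noise_sd > 0:
            y = np.clip(y + rng.normal(0.0, noise_sd, size=times.shape), 0.0, 1.0)
        rows.extend((f"rep{rep}", t, v) for t, v in zip(times, y))
    obs = pd.DataFrame(rows, columns=["replicate", "time", "value"])
    return TimeCourse(condition=condition, time_unit="minute", observations=obs,
                      assay="cleavage_fraction")


def simulate_2ap_trace(
    k: float,
    ymax: float,
    y0: float,
    interval: float = 20.0,
    duration: float = 300.0,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int | None = None,
    condition: str = "simulated",
) -> tuple[TimeCourse, TimeCourse]:
    """2AP fluorescence trace plus matching blank, sampled every ``interval`` s.

    Trace: ``Y = Y0 + Ymax*(1 - exp(-k*t))`` + noise at t = 0, interval, ...;
    blank: ``Y0`` + noise.  ``k`` is per second; fluorescence in arbitrary
    units.  Returns ``(trace, blank)`` with ``trace.blank_mean`` set to the
    mean of the blank trace.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if duration < interval:
        raise ValueError("duration must be at least one interval")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if k <= 0:
        raise ValueError("k must be positive")
    times = np.arange(0.0, duration + 0.5 * interval, interval)
    rng = np.random.default_rng(seed)

    def _rows(signal: bool) -> pd.DataFrame:
        rows = []
        for rep in range(1, n_replicates + 1):
            y = y0 + (ymax * (1.0 - np.exp(-k * times)) if signal else 0.0)
            if noise_sd > 0:
                y = y + rng.normal(0.0, noise_sd, size=times.shape)
            y = np.broadcast_to(y, times.shape)
            rows.extend((f"rep{rep}", t, v) for t, v in zip(times, y))
        return pd.DataFrame(rows, columns=["replicate", "time", "value"])

    trace_obs = _rows(signal=True)
    blank_obs = _rows(signal=False)
    blank_mean = float(blank_obs["value"].mean())
    trace = TimeCourse(condition=condition, time_unit="second", observations=trace_obs,
                       assay="fluorescence_AU", blank_mean=blank_mean)
    blank = TimeCourse(condition=f"{condition} (blank)", time_unit="second",
                       observations=blank_obs, assay="fluorescence_AU")
    return trace, blank
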