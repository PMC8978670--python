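"""Sequence-only gene-importance scoring (GIC) for lncRNAs.

The Gene Importance Calculator is a published logistic-regression score of
gene essentiality built from three kinds of sequence features: the sequence
length L (nt), the minimum free energy e of the predicted RNA secondary
structure (kcal/mol), and the overlapping-window occurrence frequencies of
five trinucleotides (CGA, GCG, TCG, ACG, TCA). The logit is

    theta = beta0 + beta1 * L + beta2 * (e / L) + sum_i alpha_i * f_i

and the score is g = 1 / (1 + exp(-theta)). Coefficients are species
presets taken from the published model, not refitted here.

MFE backends are pluggable: :class:`SurrogateMFE` is a deterministic,
dependency-free stand-in used by default (e = -0.15 kcal/mol per G or C
base); :class:`RNAfoldMFE` shells out to ViennaRNA's ``RNAfold`` when a
real folding energy is wanted.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
from dataclasses import dataclass
from typing import Mapping, Protocol

from Bio import SeqIO

from .errors import ConfigError, InvalidSequenceError

logger = logging.getLogger(__name__)

#: The five scored trinucleotides, in coefficient order alpha_1..alpha_5.
TRIPLETS = ("CGA", "GCG", "TCG", "ACG", "TCA")

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class GICCoefficients:
    """One species' logistic-model coefficients (beta_0..2, alpha_1..5)."""

    species: str
    beta0: float
    beta1: float
    beta2: float
    alphas: tuple[float, float, float, float, float]

    def __post_init__(self):
        values = (self.beta0, self.beta1, self.beta2, *self.alphas)
        if len(self.alphas) != 5:
            raise ConfigError("exactly five triplet coefficients are required")
        if not all(math.isfinite(v) for v in values):
            raise ConfigError("all GIC coefficients must be finite")

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "alphas": list(self.alphas),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GICCoefficients":
        return cls(
            species=d["species"],
            beta0=float(d["beta0"]),
            beta1=float(d["beta1"]),
            beta2=float(d["beta2"]),
            alphas=tuple(float(a) for a in d["alphas"]),
        )


MOUSE_COEFFICIENTS = GICCoefficients(
    species="mouse",
    beta0=0.1625,
    beta1=2.638e-4,
    beta2=2.194,
    alphas=(19.88, 37.59, 50.37, 35.44, -64.66),
)

HUMAN_COEFFICIENTS = GICCoefficients(
    species="human",
    beta0=0.7417,
    beta1=2.612e-4,
    beta2=4.295,
    alphas=(48.66, 15.64, 76.23, -1.113, -60.29),
)

_PRESETS = {"mouse": MOUSE_COEFFICIENTS, "human": HUMAN_COEFFICIENTS}


def coefficients_for(species: str) -> GICCoefficients:
    try:
        return _PRESETS[species]
    except KeyError:
        raise ConfigError(
            f"unknown species {species!r}; available: {sorted(_PRESETS)}"
        ) from None


def normalize_sequence(sequence: str) -> str:
    """Uppercase, map U->T, and reject anything outside A/C/G/T(/U)."""
    seq = sequence.upper().replace("U", "T")
    for pos, base in enumerate(seq):
        if base not in _VALID_BASES:
            raise InvalidSequenceError(
                f"invalid character {base!r} at position {pos + 1}"
            )
    return seq


def triplet_frequencies(sequence: str) -> tuple[float, float, float, float, float]:
    """Overlapping-window frequencies of the five scored trinucleotides.

    f_i = (count of triplet i among the L-2 overlapping windows) / (L-2).
    """
    seq = normalize_sequence(sequence)
    n_windows = len(seq) - 2
    if n_windows < 1:
        raise InvalidSequenceError(
            f"sequence too short for triplet counting (length {len(seq)} < 3)"
        )
    return tuple(_overlap_count(seq, t) / n_windows for t in TRIPLETS)


def _overlap_count(seq: str, triplet: str) -> int:
    count = start = 0
    while True:
        idx = seq.find(triplet, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


class MFEBackend(Protocol):
    name: str

    def mfe(self, sequence: str) -> float: ...


class SurrogateMFE:
    """Deterministic folding-energy stand-in: e = -0.15 * (#G + #C) kcal/mol.

    A crude GC-content proxy for stacking energy; useful wherever a real
    folding engine is unnecessary (tests, synthetic benchmarks) because it
    is fast, deterministic and has the right sign and rough length scaling.
    """

    name = "surrogate"

    def mfe(self, sequence: str) -> float:
        seq = normalize_sequence(sequence)
        return -0.15 * (seq.count("G") + seq.count("C"))


class RNAfoldMFE:
    """Minimum free energy via ViennaRNA's ``RNAfold`` executable."""

    name = "rnafold"

    def __init__(self, executable: str = "RNAfold"):
        if shutil.which(executable) is None:
            raise ConfigError(
                f"{executable!r} not found on PATH; install ViennaRNA or use "
                "the surrogate backend"
            )
        self.executable = executable

    def mfe(self, sequence: str) -> float:
        seq = normalize_sequence(sequence)
        out = subprocess.run(
            [self.executable, "--noPS"],
            input=seq + "\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout
        # last line looks like: "....(((...))). ( -12.30)"
        tail = out.strip().splitlines()[-1]
        return float(tail.rsplit("(", 1)[1].rstrip(") "))


def make_backend(name: str) -> MFEBackend:
    if name == "surrogate":
        return SurrogateMFE()
    if name == "rnafold":
        return RNAfoldMFE()
    raise ConfigError(f"unknown MFE backend {name!r}")


@dataclass(frozen=True)
class SequenceFeatures:
    """Per-sequence inputs to the logistic score."""

    length: int
    mfe: float
    frequencies: tuple[float, float, float, float, float]


@dataclass(frozen=True)
class GICResult:
    """Logit theta and score g = expit(theta) for one lncRNA."""

    theta: float
    score: float


def sequence_features(sequence: str, backend: MFEBackend) -> SequenceFeatures:
    seq = normalize_sequence(sequence)
    return SequenceFeatures(
        length=len(seq),
        mfe=backend.mfe(seq),
        frequencies=triplet_frequencies(seq),
    )


def compute_mfe(sequence: str, backend: MFEBackend) -> float:
    """Minimum free energy of the sequence under the given backend."""
    return backend.mfe(sequence)


def gic_score(features: SequenceFeatures, coeffs: GICCoefficients) -> GICResult:
    """Evaluate the logistic model on one feature vector."""
    if features.length <= 0:
        raise InvalidSequenceError("sequence length must be positive")
    theta = (
        coeffs.beta0
        + coeffs.beta1 * features.length
        + coeffs.beta2 * (features.mfe / features.length)
        + sum(a * f for a, f in zip(coeffs.alphas, features.frequencies))
    )
    # logistic; math.exp overflows around |theta| ~ 710, clamp safely
    if theta >= 0:
        score = 1.0 / (1.0 + math.exp(-min(theta, 700.0)))
    else:
        z = math.exp(max(theta, -700.0))
        score = z / (1.0 + z)
    return GICResult(theta=theta, score=score)


def score_all(
    sequences: Mapping[str, str],
    coeffs: GICCoefficients,
    backend: MFEBackend | None = None,
    cap: int = 20000,
) -> dict[str, GICResult]:
    """Score every scoreable sequence; over-length or invalid ones are skipped.

    Returns a map only for sequences with 3 <= L < cap nt whose characters
    are valid nucleotides; skipped ids are logged.
    """
    backend = backend or SurrogateMFE()
    results: dict[str, GICResult] = {}
    for name, seq in sequences.items():
        if len(seq) >= cap:
            logger.debug("skipping %s: length %d >= cap %d", name, len(seq), cap)
            continue
        try:
            results[name] = gic_score(sequence_features(seq, backend), coeffs)
        except InvalidSequenceError as exc:
            logger.warning("skipping unscoreable sequence %s: %s", name, exc)
    return results


def load_fasta(path) -> dict[str, str]:
    """Read a (possibly line-wrapped) multi-record FASTA into an id->sequence map."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
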