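"""Synthetic genomes and reads with ground truth.

The generator emulates the one property of a read set that the overlap
graph sees: exact suffix--prefix identity between reads drawn from a
common template.  Genomes are i.i.d. base strings with a controllable GC
fraction; reads are fixed-length substrings at seeded-uniform start
positions with i.i.d. substitution errors.  Ground-truth start positions
(recorded before errors are applied) let tests compare spelled walks
against the genome window they should reconstruct.

For a linear genome at finite coverage, purely uniform starts leave each
terminus uncovered with probability ~exp(-coverage/read_len); because a
terminal gap truncates the assembled sequence rather than perturbing it,
the sampler by default anchors one read at each genome end
(``anchor_ends=True``) so that error-free datasets reconstruct the full
template.  Circular genomes have no termini and are sampled purely
uniformly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .model import Read

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    genome_len: int
    read_len: int
    coverage: float
    error_rate: float
    seed: int
    circular: bool


@dataclass
class SyntheticDataset:
    """A genome, its sampled reads, and the ground-truth layout."""

    genome: str
    reads: list[Read]
    #: read id -> 0-based genome start of the read (pre-error coordinates)
    truth_positions: dict[str, int]
    params: SimParams

    def true_window(self, read_id: str) -> str:
        """Genome substring at the read's true position (with wraparound if circular)."""
        start = self.truth_positions[read_id]
        L = self.params.read_len
        g = self.genome
        if start + L <= len(g):
            return g[start : start + L]
        if not self.params.circular:
            raise ValueError(f"read {read_id} overruns a linear genome")
        return g[start:] + g[: start + L - len(g)]


def generate_genome(length: int, seed: int, gc: float = 0.5) -> str:
    """Random i.i.d. genome of exactly ``length`` bases with GC fraction ``gc``."""
    if length < 0:
        raise ParameterError(f"genome length must be >= 0, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ParameterError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]  # A C G T
    return "".join(rng.choice(_BASES, size=length, p=p))


def has_repeat(genome: str, k: int, circular: bool = False) -> bool:
    """True if any exact k-mer occurs twice (wraparound k-mers included if circular)."""
    if k < 1 or len(genome) < k:
        return False
    s = genome + genome[: k - 1] if circular else genome
    n = len(s) - k + 1
    seen: set[str] = set()
    for i in range(n):
        kmer = s[i : i + k]
        if kmer in seen:
            return True
        seen.add(kmer)
    return False


def generate_unique_genome(length: int, k: int, seed: int, gc: float = 0.5,
                           circular: bool = False, max_tries: int = 100) -> str:
    """Genome with no exact repeat of length >= k; reseeds (seed+i) until found."""
    for i in range(max_tries):
        g = generate_genome(length, seed + i, gc)
        if not has_repeat(g, k, circular=circular):
            return g
    raise ParameterError(
        f"no repeat-free genome of length {length} (k={k}) in {max_tries} tries"
    )


def sample_reads(genome: str, read_len: int, coverage: float, error_rate: float,
                 seed: int, circular: bool = False, anchor_ends: bool = True,
                 id_prefix: str = "r") -> SyntheticDataset:
    """Sample ``ceil(coverage * len(genome) / read_len)`` reads from ``genome``.

    Substitution errors hit each base independently with probability
    ``error_rate`` and change it to a uniformly chosen different base.
    """
    if read_len < 1 or read_len > len(genome):
        raise ParameterError(
            f"read_len must be in [1, genome length]; got {read_len} for genome "
            f"of {len(genome)} bp"
        )
    if coverage <= 0:
        raise ParameterError(f"coverage must be > 0, got {coverage}")
    if not 0.0 <= error_rate < 1.0:
        raise ParameterError(f"error_rate must be in [0, 1), got {error_rate}")

    n_reads = math.ceil(coverage * len(genome) / read_len)
    rng = np.random.default_rng(seed)
    high = len(genome) if circular else len(genome) - read_len + 1
    starts = rng.integers(0, high, size=n_reads)
    if not circular and anchor_ends and n_reads >= 2:
        starts[0] = 0
        starts[1] = len(genome) - read_len

    width = max(5, len(str(n_reads)))
    reads: list[Read] = []
    truth: dict[str, int] = {}
    for i, start in enumerate(starts):
        start = int(start)
        rid = f"{id_prefix}{i + 1:0{width}d}"
        if start + read_len <= len(genome):
            seq = genome[start : start + read_len]
        else:
            seq = genome[start:] + genome[: start + read_len - len(genome)]
        if error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
            hits = np.nonzero(rng.random(read_len) < error_rate)[0]
            for j in hits:
                alternatives = [b for b in "ACGT" if b != arr[j]]
                arr[j] = alternatives[rng.integers(0, 3)]
            seq = "".join(arr)
        reads.append(Read(rid, seq))
        truth[rid] = start

    params = SimParams(len(genome), read_len, coverage, error_rate, seed, circular)
    return SyntheticDataset(genome, reads, truth, params)
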