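"""Bridge-adapter chimeric read parsing and exact-match unique alignment.

Proximity-ligation libraries (Red-C / RedChIP style) place a fixed bridge
oligonucleotide between a DNA fragment and the 5' end of an RNA fragment.
This module locates the bridge inside a read (allowing mismatches), splits
the read into its DNA and RNA parts, validates the 3'-RNA mate, removes
exact duplicate pairs and maps parts to unique genomic loci.

The built-in aligner is exact-match and unique-hit only; it is sufficient
for synthetic genomes without repeats.  Real data would go through a
splice-aware external aligner behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

DEFAULT_BRIDGE = "AGTCGGAGCGTTGCCTATCGCATTGATGGTGCTAGGA"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BridgeSpec:
    """The bridge oligonucleotide and the mismatch budget for finding it."""

    bridge_sequence: str = DEFAULT_BRIDGE
    max_mismatches: int = 4

    def __post_init__(self):
        if set(self.bridge_sequence) - set("ACGT"):
            raise ValueError("bridge must be over the ACGT alphabet")
        if len(self.bridge_sequence) < self.max_mismatches + 10:
            raise ValueError("bridge too short for the mismatch budget")


@dataclass(frozen=True)
class SplitConfig:
    """Read-splitting parameters (cutadapt-style -m / -O / -e)."""

    min_part_length: int = 14
    min_overlap: int = 37
    error_rate: float = 0.11

    def __post_init__(self):
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.min_part_length < 1:
            raise ValueError("min_part_length must be >= 1")


@dataclass(frozen=True)
class BridgeHit:
    orientation: str  # "forward" | "reverse"
    offset: int  # 0-based position of the bridge copy in the read
    mismatches: int


@dataclass(frozen=True)
class SplitRead:
    read_id: str
    dna_part: str
    rna5_part: str
    orientation: str
    bridge_offset: int
    bridge_mismatches: int


def _hamming(a: str, b: str) -> int:
    # N counts as a mismatch because it never equals an ACGT bridge base.
    return sum(x != y for x, y in zip(a, b))


def find_bridge(read: str, spec: BridgeSpec = BridgeSpec()) -> BridgeHit | None:
    """Best full-length occurrence of the bridge or its reverse complement.

    Returns the hit minimising (mismatches, offset, orientation) with
    forward ranked before reverse, or None when the minimum exceeds
    ``spec.max_mismatches``.  Reads shorter than the bridge yield None.
    Only full-length occurrences count; partial terminal overlaps are
    rejected.
    """
    bridge = spec.bridge_sequence
    rc = revcomp(bridge)
    n, m = len(read), len(bridge)
    if n < m:
        return None
    best: tuple[int, int, int] | None = None  # (mm, offset, orient_rank)
    for off in range(n - m + 1):
        window = read[off : off + m]
        for rank, pattern in ((0, bridge), (1, rc)):
            mm = _hamming(window, pattern)
            key = (mm, off, rank)
            if best is None or key < best:
                best = key
    if best is None or best[0] > spec.max_mismatches:
        return None
    return BridgeHit("forward" if best[2] == 0 else "reverse", best[1], best[0])


# ---------------------------------------------------------------------------
# Vectorised batch bridge search (same contract as find_bridge, for pipelines)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _ENCODE[ord(base)] = i
    _ENCODE[ord(base.lower())] = i


def encode_reads(reads: Sequence[str]) -> np.ndarray:
    """Encode equal-length reads into a (n_reads, read_len) uint8 matrix."""
    if not reads:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(reads[0])
    if any(len(r) != length for r in reads):
        raise ValueError("batch encoding requires equal-length reads")
    buf = np.frombuffer("".join(reads).encode("ascii"), dtype=np.uint8)
    return _ENCODE[buf].reshape(len(reads), length)


def find_bridge_batch(reads: Sequence[str], spec: BridgeSpec = BridgeSpec()):
    """Vectorised find_bridge over equal-length reads.

    Returns (orientation_codes, offsets, mismatches) int arrays; orientation
    -1 marks "no hit", 0 forward, 1 reverse.
    """
    mat = encode_reads(reads)
    n, length = mat.shape
    m = len(spec.bridge_sequence)
    ori = np.full(n, -1, dtype=np.int8)
    off = np.full(n, -1, dtype=np.int64)
    mm = np.full(n, m + 1, dtype=np.int64)
    if length < m or n == 0:
        return ori, off, mm
    fwd = _ENCODE[np.frombuffer(spec.bridge_sequence.encode(), np.uint8)]
    rev = _ENCODE[np.frombuffer(revcomp(spec.bridge_sequence).encode(), np.uint8)]
    for o in range(length - m + 1):
        window = mat[:, o : o + m]
        for rank, pattern in ((0, fwd), (1, rev)):
            d = (window != pattern).sum(axis=1)
            better = d < mm  # ascending (offset, rank) scan => lexicographic min
            mm[better] = d[better]
            off[better] = o
            ori[better] = rank
    miss = mm > spec.max_mismatches
    ori[miss], off[miss], mm[miss] = -1, -1, m + 1
    return ori, off, mm


def validate_rna3(read: str) -> bool:
    """True iff the 3'-RNA mate starts with GGG or ends with CCC."""
    if not read:
        raise ValueError("empty read")
    return read.startswith("GGG") or read.endswith("CCC")


def trim_rna3_anchor(read: str) -> str:
    """Strip the 3-nt GGG/CCC anchor so the remainder is genomic sequence."""
    if read.startswith("GGG"):
        return read[3:]
    if read.endswith("CCC"):
        return read[:-3]
    return read


def split_at_bridge(
    read: str,
    hit: BridgeHit,
    cfg: SplitConfig = SplitConfig(),
    spec: BridgeSpec = BridgeSpec(),
    read_id: str = "",
) -> SplitRead | None:
    """Split a read around a bridge hit into DNA and 5'-RNA parts.

    Forward hits: upstream of the bridge is the DNA part, downstream the
    RNA part.  Reverse hits are handled by reverse-complementing the read
    and applying the forward rule.  Parts shorter than
    ``cfg.min_part_length`` discard the read (returns None).
    """
    m = len(spec.bridge_sequence)
    if hit.offset < 0 or hit.offset + m > len(read):
        raise ValueError("bridge hit offset out of read bounds")
    if hit.mismatches > int(cfg.error_rate * m):
        # more mismatches than the split error rate permits
        return None
    if hit.orientation == "reverse":
        seq = revcomp(read)
        offset = len(read) - hit.offset - m
    else:
        seq = read
        offset = hit.offset
    dna = seq[:offset]
    rna = seq[offset + m :]
    if len(dna) < cfg.min_part_length or len(rna) < cfg.min_part_length:
        return None
    return SplitRead(read_id, dna, rna, hit.orientation, hit.offset, hit.mismatches)


def dedup_reads(pairs: Iterable[tuple[str, str]]) -> list[tuple[str, str]]:
    """Collapse exact duplicate pairs, keeping first occurrence order."""
    seen: set[tuple[str, str]] = set()
    out = []
    for pair in pairs:
        key = (pair[0], pair[1])
        if key not in seen:
            seen.add(key)
            out.append(pair)
    return out


# ---------------------------------------------------------------------------
# Exact-match unique alignment


class GenomeIndex:
    """Sorted k-mer index over a set of chromosomes for exact unique lookup.

    Occurrence search verifies full-length exact matches of a query (and its
    reverse complement) seeded from the query's first k bases.
    """

    def __init__(self, genome: dict[str, str], k: int = 14):
        self.genome = genome
        self.k = k
        self.chroms = list(genome)
        codes_parts, pos_parts = [], []
        self._offsets = {}
        offset = 0
        for chrom in self.chroms:
            seq = genome[chrom]
            self._offsets[chrom] = offset
            b = _ENCODE[np.frombuffer(seq.encode("ascii"), np.uint8)].astype(np.uint64)
            n = len(seq)
            if n >= k:
                c = np.zeros(n - k + 1, dtype=np.uint64)
                for j in range(k):
                    c = (c << np.uint64(2)) | b[j : n - k + 1 + j]
                codes_parts.append(c)
                pos_parts.append(np.arange(offset, offset + n - k + 1, dtype=np.int64))
            offset += n
        self._bounds = np.array(
            [self._offsets[c] for c in self.chroms] + [offset], dtype=np.int64
        )
        codes = np.concatenate(codes_parts) if codes_parts else np.empty(0, np.uint64)
        pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]

    def encode_kmer(self, kmer: str) -> int | None:
        b = _ENCODE[np.frombuffer(kmer.encode("ascii"), np.uint8)]
        if (b > 3).any():
            return None
        code = 0
        for v in b:
            code = (code << 2) | int(v)
        return code

    def _decode(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self._bounds, gpos, "right")) - 1
        return self.chroms[i], gpos - int(self._bounds[i])

    def occurrences(self, query: str) -> list[tuple[str, int, str]]:
        """All exact full-length occurrences of query on either strand."""
        hits = []
        patterns = [(query, "+")]
        rc = revcomp(query)
        if rc != query:
            patterns.append((rc, "-"))
        for pattern, strand in patterns:
            code = self.encode_kmer(pattern[: self.k])
            if code is None:
                continue
            lo = np.searchsorted(self._codes, np.uint64(code), "left")
            hi = np.searchsorted(self._codes, np.uint64(code), "right")
            for gpos in self._pos[lo:hi]:
                chrom, p = self._decode(int(gpos))
                seq = self.genome[chrom]
                if seq[p : p + len(pattern)] == pattern:
                    hits.append((chrom, p, strand))
        return hits

    def align_unique(self, part: str) -> tuple[str, int, str] | None:
        """Locus of a uniquely mapping part, or None (multi/non-mapper)."""
        if not part:
            raise ValueError("empty part")
        if len(part) < self.k:
            raise ValueError(f"part shorter than index k={self.k}")
        hits = self.occurrences(part)
        return hits[0] if len(hits) == 1 else None


def align_unique(part: str, index: GenomeIndex) -> tuple[str, int, str] | None:
    """Functional wrapper over :meth:`GenomeIndex.align_unique`."""
    return index.align_unique(part)
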