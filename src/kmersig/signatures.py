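"""k-tuple sequence signatures of read sets.

A sample's signature is the vector of counts (or frequencies) of all 4**k
nucleotide words of length k across its reads.  Reads are supplemented with
their reverse complements before counting so that both strands contribute,
which makes every signature strand-symmetric.

Tuples are indexed lexicographically with A < C < G < T (A=0, C=1, G=2,
T=3); the index of w = w1..wk is sum(code(wj) * 4**(k-j)).  This ordering is
fixed across the whole package.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "ReadSet",
    "KmerCountVector",
    "KmerFrequencyVector",
    "load_reads",
    "supplement_complements",
    "count_kmers",
    "count_pattern",
    "to_frequencies",
    "kmer_strings",
    "index_to_kmer",
    "kmer_to_index",
    "write_signature_tsv",
]

ALPHABET = "ACGT"
DEFAULT_MAX_K = 12

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> 2-bit code; anything outside ACGT maps to -1 and invalidates
# every window that covers it
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class ReadSet:
    """An ordered collection of reads from one sample."""

    sample_id: str
    reads: list[str]
    supplemented: bool = False

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class KmerCountVector:
    """Counts of all 4**k tuples; ``n`` is the total number of counted windows."""

    k: int
    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.k,):
            raise ValueError(
                f"counts must have length 4**{self.k}, got {self.counts.shape}"
            )


@dataclass
class KmerFrequencyVector:
    k: int
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.shape != (4**self.k,):
            raise ValueError(
                f"freqs must have length 4**{self.k}, got {self.freqs.shape}"
            )


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_reads(path: str | Path, format: str = "fasta", sample_id: str | None = None) -> ReadSet:
    """Load a FASTA or FASTQ file (optionally gzipped) into a ReadSet.

    Sequences are uppercased; FASTQ qualities are discarded.  Raises
    ValueError on an empty file or a malformed record (the error names the
    failing record index).
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}; use 'fasta' or 'fastq'")
    path = Path(path)
    if sample_id is None:
        name = path.name
        for suf in (".gz", ".fasta", ".fastq", ".fa", ".fq"):
            if name.endswith(suf):
                name = name[: -len(suf)]
        sample_id = name
    reads: list[str] = []
    with _open_maybe_gzip(path) as handle:
        records = SeqIO.parse(handle, format)
        idx = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed {format} record at index {idx} in {path}: {exc}") from exc
            reads.append(str(rec.seq).upper())
            idx += 1
    if not reads:
        raise ValueError(f"no records found in {path}")
    return ReadSet(sample_id=sample_id, reads=reads)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def supplement_complements(rs: ReadSet, reverse: bool = True) -> ReadSet:
    """Return a new ReadSet with each read followed by its complement.

    ``reverse=True`` (default) appends reverse complements, i.e. the
    sequence actually present on the opposite strand; ``reverse=False``
    appends base-wise complements without reversal.
    """
    if rs.supplemented:
        raise ValueError(f"read set {rs.sample_id!r} is already supplemented")
    if reverse:
        extra = [reverse_complement(r) for r in rs.reads]
    else:
        extra = [r.translate(_COMPLEMENT) for r in rs.reads]
    return ReadSet(sample_id=rs.sample_id, reads=rs.reads + extra, supplemented=True)


def _encode_reads(rs: ReadSet | Sequence[str]) -> np.ndarray:
    """Concatenate reads into one int8 code array with -1 sentinels between
    reads so that no window spans a read boundary.  Cached on ReadSet
    instances since counting at several k re-uses the same encoding."""
    if isinstance(rs, ReadSet):
        cached = getattr(rs, "_encoded", None)
        if cached is not None:
            return cached
        reads = rs.reads
    else:
        reads = rs
    blob = "\x00".join(reads).encode("ascii")
    arr = _CODE[np.frombuffer(blob, dtype=np.uint8)]
    if isinstance(rs, ReadSet):
        rs._encoded = arr
    return arr


def _window_index_counts(arr: np.ndarray, offsets: Sequence[int]) -> tuple[np.ndarray, int]:
    """Count words read at ``offsets`` within every fully-valid window.

    A window of span offsets[-1]+1 is valid only if every position in the
    span is an unambiguous ACGT base.  Returns (counts over 4**len(offsets)
    words, number of valid windows).
    """
    span = offsets[-1] + 1
    m = arr.size - span + 1
    dim = 4 ** len(offsets)
    if m <= 0:
        return np.zeros(dim, dtype=np.int64), 0
    valid = np.ones(m, dtype=bool)
    for j in range(span):
        valid &= arr[j : j + m] >= 0
    idx = np.zeros(m, dtype=np.int64)
    for o in offsets:
        idx = idx * 4 + arr[o : o + m]
    idx = idx[valid]
    counts = np.bincount(idx, minlength=dim).astype(np.int64)
    return counts, int(idx.size)


def count_kmers(rs: ReadSet, k: int, max_k: int = DEFAULT_MAX_K) -> KmerCountVector:
    """Count every length-k window fully inside a read.

    Windows containing any non-ACGT character are skipped.  If k exceeds
    every read length the result is an all-zero vector with n = 0.
    """
    if not rs.supplemented:
        raise ValueError("read set must be supplemented before counting")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > max_k:
        raise ValueError(f"k={k} exceeds max_k={max_k}; pass max_k explicitly to override")
    arr = _encode_reads(rs)
    counts, n = _window_index_counts(arr, range(k))
    return KmerCountVector(k=k, counts=counts, n=n)


def count_pattern(rs: ReadSet, offsets: Sequence[int]) -> tuple[np.ndarray, int]:
    """Count gapped words (e.g. offsets (0, 2) = X·Z over span-3 windows).

    Used for the relative-abundance odds ratios; windows are taken over the
    full span and must be entirely unambiguous.
    """
    offsets = tuple(offsets)
    if not offsets or offsets[0] != 0 or list(offsets) != sorted(set(offsets)):
        raise ValueError("offsets must be strictly increasing and start at 0")
    return _window_index_counts(_encode_reads(rs), offsets)


def to_frequencies(cv: KmerCountVector) -> KmerFrequencyVector:
    if cv.n <= 0:
        raise ValueError("empty signature: total tuple count is 0")
    return KmerFrequencyVector(k=cv.k, freqs=cv.counts / cv.n)


def kmer_strings(k: int) -> list[str]:
    """All 4**k tuples in lexicographic index order."""
    return [index_to_kmer(i, k) for i in range(4**k)]


def index_to_kmer(index: int, k: int) -> str:
    letters = []
    for _ in range(k):
        letters.append(ALPHABET[index % 4])
        index //= 4
    return "".join(reversed(letters))


def kmer_to_index(word: str) -> int:
    idx = 0
    for ch in word:
        pos = ALPHABET.find(ch)
        if pos < 0:
            raise ValueError(f"non-ACGT character {ch!r} in tuple {word!r}")
        idx = idx * 4 + pos
    return idx


def write_signature_tsv(cv: KmerCountVector, path: str | Path) -> None:
    """Write tuple / count / frequency as TSV (frequency blank when n = 0)."""
    with open(path, "w") as fh:
        fh.write("tuple\tcount\tfrequency\n")
        for i, word in enumerate(kmer_strings(cv.k)):
            c = int(cv.counts[i])
            freq = f"{c / cv.n:.10g}" if cv.n > 0 else ""
            fh.write(f"{word}\t{c}\t{freq}\n")


def read_signature_tsv(path: str | Path) -> KmerCountVector:
    counts = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("tuple\t"):
            raise ValueError(f"{path}: not a signature TSV")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            counts.append(int(parts[1]))
    dim = len(counts)
    k = round(np.log(dim) / np.log(4))
    if 4**k != dim:
        raise ValueError(f"{path}: {dim} rows is not a power of 4")
    arr = np.asarray(counts, dtype=np.int64)
    return KmerCountVector(k=k, counts=arr, n=int(arr.sum()))
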