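"""Genome sequences as integer-coded arrays with k-mer context accessors.

Sequences are stored per chromosome as ``uint8`` arrays with A=0, C=1,
G=2, T=3 and N (or any ambiguity code)=4.  All genomic coordinates in the
package are 0-based, half-open.  The k-mer context of a site is the window
of ``k`` bases centred on it; contexts touching a contig edge or containing
an N are undefined and are excluded from all tallies.
"""

from __future__ import annotations

import numpy as np
from pyfaidx import Fasta

BASES = "ACGT"
A, C, G, T, N = 0, 1, 2, 3, 4

_CODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_CHAR = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes (N for anything odd)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    return _CHAR[codes].tobytes().decode("ascii")


def revcomp_str(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    ok = out < 4
    out[ok] = 3 - out[ok]
    return out


def kmer_to_code(kmer: str) -> int:
    """Map a k-mer string (no N) to its integer code in [0, 4**k)."""
    code = 0
    for b in kmer:
        code = code * 4 + BASES.index(b.upper())
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def central_base(code: int | np.ndarray, k: int):
    """Code (0-3) of the central base of a k-mer code."""
    h = (k - 1) // 2
    return (code // 4 ** (k - 1 - h)) % 4


def kmer_digit(code: int | np.ndarray, k: int, d: int):
    """Code of base at position d (0 = 5'-most) of a k-mer code."""
    return (code // 4 ** (k - 1 - d)) % 4


class Genome:
    """In-memory genome: ``{chrom: uint8 codes}`` plus context-code caches."""

    def __init__(self, seqs: dict[str, np.ndarray]):
        self.seqs = {c: np.asarray(s, dtype=np.uint8) for c, s in seqs.items()}
        self._ctx_cache: dict[tuple[str, int, str], np.ndarray] = {}

    @classmethod
    def from_strings(cls, seqs: dict[str, str]) -> "Genome":
        return cls({c: encode(s) for c, s in seqs.items()})

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        fa = Fasta(str(path), as_raw=True, rebuild=True)
        return cls.from_strings({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                fh.write(f">{chrom}\n")
                s = decode(self.seqs[chrom])
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")

    @property
    def chroms(self) -> list[str]:
        return list(self.seqs.keys())

    def __len__(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    def sequence(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        return decode(self.seqs[chrom][start:end])

    def context_codes(self, chrom: str, k: int, strand: str = "+") -> np.ndarray:
        """Per-position k-mer context codes on the requested strand.

        Returns an int32 array of the chromosome length; -1 marks positions
        whose context is undefined (contig edge or contains N).  On the "-"
        strand, the code is that of the reverse-complemented k-mer, i.e. the
        context as read on the minus strand centred on the same position.
        """
        if k % 2 != 1 or k < 1:
            raise ValueError("k must be odd and >= 1")
        key = (chrom, k, strand)
        if key not in self._ctx_cache:
            self._ctx_cache[key] = self._compute_ctx(chrom, k, strand)
        return self._ctx_cache[key]

    def _compute_ctx(self, chrom: str, k: int, strand: str) -> np.ndarray:
        codes = self.seqs[chrom]
        L = len(codes)
        h = (k - 1) // 2
        out = np.zeros(L, dtype=np.int64)
        bad = np.zeros(L, dtype=bool)
        for d in range(k):  # d = 0 is the 5'-most base on the plus strand
            off = d - h
            shifted = np.full(L, N, dtype=np.uint8)
            lo, hi = max(0, -off), min(L, L - off)
            shifted[lo:hi] = codes[lo + off : hi + off]
            bad |= shifted >= 4
            digit = shifted.astype(np.int64)
            digit[digit >= 4] = 0
            if strand == "+":
                out += digit * 4 ** (k - 1 - d)
            else:
                # reverse complement: position d maps to rc position k-1-d
                out += (3 - digit) * 4 ** (d)
        out[bad] = -1
        return out.astype(np.int32)
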