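"""Low-level nucleotide encoding and k-mer code tables.

Sequences are encoded as uint8 arrays with A=0, C=1, G=2, T=3 and N=4.
A k-mer starting at position p is summarised by an integer code
``sum(base[p+j] * 4**(k-1-j))`` (first base most significant); windows
containing an N carry code -1 and are excluded from all counts.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.array(list("ACGTN"))

#: IUPAC symbol -> frozenset of concrete bases (indices into ACGT)
IUPAC_SETS: dict[str, frozenset[int]] = {
    "A": frozenset({0}), "C": frozenset({1}), "G": frozenset({2}),
    "T": frozenset({3}),
    "R": frozenset({0, 2}), "Y": frozenset({1, 3}), "S": frozenset({1, 2}),
    "W": frozenset({0, 3}), "K": frozenset({2, 3}), "M": frozenset({0, 1}),
    "B": frozenset({1, 2, 3}), "D": frozenset({0, 2, 3}),
    "H": frozenset({0, 1, 3}), "V": frozenset({0, 1, 2}),
    "N": frozenset({0, 1, 2, 3}),
}

#: complement of each IUPAC symbol
IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

DEGENERATE_CODES = "RYSWKMBDHVN"  # the 11 non-concrete IUPAC symbols


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (N and unknowns -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return "".join(_DECODE[arr])


def kmer_codes(enc: np.ndarray, k: int, circular: bool = False) -> np.ndarray:
    """Integer code of the k-mer starting at each position.

    Returns an int64 array of length ``len(enc)`` if circular (windows wrap)
    or ``len(enc) - k + 1`` otherwise; windows containing N get code -1.
    """
    if circular:
        enc = np.concatenate([enc, enc[: k - 1]])
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        col = enc[j : j + n].astype(np.int64)
        bad |= col == 4
        codes = codes * 4 + np.where(col == 4, 0, col)
    codes[bad] = -1
    return codes


def revcomp_code(k: int) -> np.ndarray:
    """Permutation p with p[code(w)] == code(reverse complement of w)."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    for j in range(k):
        base = (codes >> (2 * (k - 1 - j))) & 3  # base at position j
        rc += (3 - base) << (2 * j)  # goes to position k-1-j
    return rc


def code_of(kmer: str) -> int:
    """Code of a concrete k-mer string."""
    c = 0
    for ch in kmer.upper():
        b = "ACGT".index(ch)
        c = c * 4 + b
    return c


def string_of(code: int, k: int) -> str:
    out = []
    for j in range(k):
        out.append("ACGT"[(code >> (2 * (k - 1 - j))) & 3])
    return "".join(out)


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))


def expand_degenerate(pattern: str) -> list[int]:
    """All concrete k-mer codes matching an IUPAC pattern."""
    codes = [0]
    for ch in pattern.upper():
        bases = sorted(IUPAC_SETS[ch])
        codes = [c * 4 + b for c in codes for b in bases]
    return codes


def bincount_codes(codes: np.ndarray, size: int) -> np.ndarray:
    """Count k-mer codes, ignoring masked (-1) windows."""
    valid = codes[codes >= 0]
    return np.bincount(valid, minlength=size).astype(np.int64)
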