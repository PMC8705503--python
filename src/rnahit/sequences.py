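"""Fixed-length RNA sequence space with Hamming geometry.

Sequences of length ``n`` over the alphabet {A, U, G, C} are encoded as
base-4 integers (A=0, U=1, G=2, C=3), two bits per position.  With this
coding Watson–Crick complementation (A<->U, C<->G, element-wise, *not*
reverse-complement) is a XOR with the mask ``0b0101...01``: the pairs
(0,1) and (2,3) swap under XOR 1.  The complement therefore has no fixed
point and ``h(x, xc) = n`` for every sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

ALPHABET = "AUGC"
_CODE = {b: i for i, b in enumerate(ALPHABET)}

#: Full-space enumeration guard: operations materializing all 4**n sequences
#: refuse to run above this dimension unless the caller raises the cap.
DEFAULT_ENUMERATION_CAP = 8


class SequenceError(ValueError):
    """Invalid sequence input (bad symbol, length mismatch, empty set)."""


def encode(seq: str) -> int:
    """Encode a string over {A,U,G,C} as a base-4 integer code.

    Position 0 of the string occupies the least-significant digit.
    """
    code = 0
    for i, b in enumerate(seq):
        try:
            code |= _CODE[b] << (2 * i)
        except KeyError:
            raise SequenceError(
                f"invalid base {b!r} at position {i}; expected one of {ALPHABET}"
            ) from None
    return code


def decode(code: int, n: int) -> str:
    """Decode an integer code back to a length-``n`` string."""
    if not 0 <= code < 4**n:
        raise SequenceError(f"code {code} out of range for n={n}")
    return "".join(ALPHABET[(code >> (2 * i)) & 3] for i in range(n))


def complement_mask(n: int) -> int:
    """XOR mask implementing element-wise complementation for length n."""
    mask = 0
    for i in range(n):
        mask |= 1 << (2 * i)
    return mask


def complement(code: int, n: int) -> int:
    """Element-wise complement: A<->U, C<->G.  An involution."""
    return code ^ complement_mask(n)


def hamming(a: int, b: int, n: int) -> int:
    """Hamming distance between two encoded sequences of length n."""
    d = a ^ b
    # a position differs iff its 2-bit group is nonzero
    g = (d | (d >> 1)) & complement_mask(n)
    return bin(g).count("1")


def hamming_str(x: str, y: str) -> int:
    """Hamming distance between two sequence strings of equal length."""
    if len(x) != len(y):
        raise SequenceError(f"length mismatch: {len(x)} vs {len(y)}")
    return hamming(encode(x), encode(y), len(x))


def complement_str(x: str) -> str:
    """Element-wise complement of a sequence string."""
    return decode(complement(encode(x), len(x)), len(x))


@dataclass
class LevelSetPartition:
    """Partition of sequence space into Hamming level sets.

    For a single template ``y`` the class ``H_i`` collects sequences at
    Hamming distance ``i`` from the template's complement ``yc``; class
    sizes are ``C(n,i) * 3**i``.  For a manifold ``R`` the class of ``x``
    is ``min(H(x,R), H(xc,R))`` so that a strand and its complement share
    a class.
    """

    n: int
    class_of: np.ndarray  # int array of length 4**n
    classes: list = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = [
                np.flatnonzero(self.class_of == i) for i in range(self.n + 1)
            ]

    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.classes])

    def members(self, i: int) -> np.ndarray:
        return self.classes[i]


class SequenceSpace:
    """The space E = {A,U,G,C}^n with cached complement and distance tables.

    Parameters
    ----------
    n : int
        Sequence length (the "sequence dimension").
    cap : int
        Maximum n for which full-space (4**n) enumeration tables are
        permitted; pairwise distance queries remain available above it.
    """

    def __init__(self, n: int, cap: int = DEFAULT_ENUMERATION_CAP):
        if n < 1:
            raise SequenceError("sequence dimension n must be >= 1")
        self.n = int(n)
        self.cap = int(cap)
        self.mask = complement_mask(self.n)
        self._hamming_table: np.ndarray | None = None
        self._digit_weight: np.ndarray | None = None

    # -- basic geometry -------------------------------------------------

    @property
    def size(self) -> int:
        return 4**self.n

    @property
    def enumerable(self) -> bool:
        return self.n <= self.cap

    def _require_enumerable(self, what: str) -> None:
        if not self.enumerable:
            raise SequenceError(
                f"{what} enumerates all 4^{self.n} sequences; raise cap "
                f"(currently {self.cap}) or use streaming/sampling APIs"
            )

    def codes(self) -> np.ndarray:
        self._require_enumerable("codes()")
        return np.arange(self.size, dtype=np.int64)

    @property
    def complement_perm(self) -> np.ndarray:
        """Permutation array mapping each code to its complement."""
        self._require_enumerable("complement_perm")
        return np.arange(self.size, dtype=np.int64) ^ self.mask

    def complement(self, code):
        return code ^ self.mask

    def hamming(self, a, b):
        """Hamming distance; accepts scalars or numpy arrays (broadcast)."""
        d = np.bitwise_xor(a, b)
        g = (d | (d >> 1)) & self.mask
        if self._digit_weight is None:
            # popcount over per-position difference indicators
            self._digit_weight = np.array(
                [bin(v).count("1") for v in range(1 << self.n)], dtype=np.int64
            )
        # compress 2-bit groups: bit i of the index is bit 2i of g
        g = np.asarray(g)
        idx = np.zeros_like(g)
        for i in range(self.n):
            idx |= ((g >> (2 * i)) & 1) << i
        out = self._digit_weight[idx]
        return int(out) if out.ndim == 0 else out

    @property
    def hamming_table(self) -> np.ndarray:
        """Dense (4^n, 4^n) pairwise Hamming distance table."""
        self._require_enumerable("hamming_table")
        if self._hamming_table is None:
            codes = np.arange(self.size, dtype=np.int64)
            self._hamming_table = self.hamming(codes[:, None], codes[None, :])
        return self._hamming_table

    # -- manifold distances ---------------------------------------------

    def manifold_distance(self, code, R):
        """H(x, R) = min over y in R of h(x, y).  R must be non-empty."""
        R = np.atleast_1d(np.asarray(R, dtype=np.int64))
        if R.size == 0:
            raise SequenceError("high-fidelity set R must be non-empty")
        scalar = np.ndim(code) == 0
        c = np.atleast_1d(np.asarray(code, dtype=np.int64))
        d = self.hamming(c[:, None], R[None, :])
        out = np.atleast_1d(d).reshape(c.size, R.size).min(axis=1)
        return int(out[0]) if scalar else out

    def spatial_distance(self, a, b):
        """S(x,y): min of the four Hamming distances among strands and
        complements.  Symmetric, invariant to complementing either
        argument; S(x, xc) = 0."""
        ac, bc = self.complement(a), self.complement(b)
        return np.minimum.reduce(
            [self.hamming(a, b), self.hamming(a, bc),
             self.hamming(ac, b), self.hamming(ac, bc)]
        )

    # -- level sets -----------------------------------------------------

    def level_sets(self, reference) -> LevelSetPartition:
        """Level-set partition of E.

        ``reference`` is either a single template code (classes by
        distance to its complement) or an array of manifold codes
        (classes by ``min(H(x,R), H(xc,R))``).
        """
        self._require_enumerable("level_sets")
        codes = np.arange(self.size, dtype=np.int64)
        if np.ndim(reference) == 0:
            yc = self.complement(int(reference))
            cls = self.hamming(codes, yc)
        else:
            H = self.manifold_distance(codes, reference)
            Hc = H[self.complement_perm]
            cls = np.minimum(H, Hc)
        return LevelSetPartition(self.n, np.asarray(cls))


# -- FASTA I/O -----------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file; validates the alphabet."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        encode(seq)  # validation
        records.append((rec.id, seq))
    return records


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs to FASTA.  The id may carry count
    annotations like ``seq3|count=5``."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")
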