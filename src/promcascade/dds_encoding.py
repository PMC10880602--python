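"""DNA duplex stability (DDS) encoding of nucleotide sequences.

A sequence of length *n* is represented by the *n − 1* free-energy values of
its overlapping dinucleotide steps, read 5'→3'.  AT-rich promoter elements
(the −10 and −35 boxes recognised by the RNA polymerase σ subunit) form fewer
hydrogen bonds and are thermodynamically less stable than GC-rich background,
so the encoding exposes promoter architecture to a classifier without any
motif model.

The default parameter set is the unified nearest-neighbor ΔG°37 scale
(kcal/mol), shipped as a data file; every operation accepts an alternative
:class:`DDSTable`, keeping the thermodynamic scale swappable and auditable.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AlphabetError, FormatError, LengthError, ShapeError

BASES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_TABLE_RESOURCE = "dds_unified_dg37.tsv"


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string (uppercase in, uppercase out)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DDSTable:
    """Dinucleotide → duplex-stability lookup (free energy, kcal/mol).

    Parameters
    ----------
    values
        Map from each of the 16 dinucleotides (5'→3', uppercase) to a finite
        stability value.
    name
        Identifier of the parameter set.
    source
        Citation string for the parameter set.
    """

    values: Mapping[str, float]
    name: str = "custom"
    source: str = ""

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(DINUCLEOTIDES):
            missing = sorted(set(DINUCLEOTIDES) - keys)
            extra = sorted(keys - set(DINUCLEOTIDES))
            raise FormatError(
                f"DDS table must have exactly the 16 ACGT dinucleotides; "
                f"missing={missing} extra={extra}"
            )
        for k, v in self.values.items():
            if not math.isfinite(float(v)):
                raise FormatError(f"non-finite DDS value for {k}: {v!r}")

    def __getitem__(self, dinucleotide: str) -> float:
        return float(self.values[dinucleotide])

    def is_complement_symmetric(self, tol: float = 1e-9) -> bool:
        """True when value(XY) == value(reverse_complement(XY)) for all steps."""
        return all(
            abs(self[d] - self[reverse_complement(d)]) <= tol for d in DINUCLEOTIDES
        )

    def lookup_array(self) -> np.ndarray:
        """Length-16 array indexed by 4*code(first) + code(second), A,C,G,T → 0..3."""
        return np.array([self[d] for d in DINUCLEOTIDES], dtype=np.float64)

    def mean_value(self) -> float:
        """Arithmetic mean of the 16 values (used for permissive imputation)."""
        return float(np.mean(self.lookup_array()))

    def checksum(self) -> str:
        """SHA-256 over the canonical serialisation; identifies the parameter set."""
        canon = ";".join(f"{d}={self[d]:.10g}" for d in DINUCLEOTIDES)
        return hashlib.sha256(canon.encode()).hexdigest()

    def to_dict(self) -> dict:
        return {
            "values": {d: self[d] for d in DINUCLEOTIDES},
            "name": self.name,
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DDSTable":
        return cls(values=dict(d["values"]), name=d.get("name", "custom"),
                   source=d.get("source", ""))


@dataclass
class FeatureVector:
    """Per-step DDS values for one sequence, ordered 5'→3'."""

    values: np.ndarray
    sequence_id: str = ""
    n_imputed: int = 0  # steps filled with the table mean in permissive mode

    def __len__(self) -> int:
        return len(self.values)


def _parse_table_lines(lines: Iterable[str], name: str, source: str) -> DDSTable:
    values: dict[str, float] = {}
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: expected 'dinucleotide<TAB>value', got {raw!r}")
        dinuc, val = parts[0].upper(), parts[1]
        if dinuc in values:
            raise FormatError(f"line {lineno}: duplicate dinucleotide {dinuc}")
        if dinuc not in DINUCLEOTIDES:
            raise FormatError(f"line {lineno}: {dinuc!r} is not an ACGT dinucleotide")
        try:
            values[dinuc] = float(val)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric value {val!r}") from exc
    return DDSTable(values=values, name=name, source=source)


def load_dds_table(path, name: str | None = None, source: str = "") -> DDSTable:
    """Read a 2-column ``dinucleotide<TAB>value`` file (16 data rows, # comments).

    Raises :class:`FormatError` on missing/duplicate dinucleotides or
    non-numeric values.
    """
    with open(path) as fh:
        return _parse_table_lines(fh, name or str(path), source)


_DEFAULT_TABLE: DDSTable | None = None


def default_table() -> DDSTable:
    """The packaged unified nearest-neighbor ΔG°37 table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        text = (
            resources.files("promcascade.data")
            .joinpath(DEFAULT_TABLE_RESOURCE)
            .read_text()
        )
        _DEFAULT_TABLE = _parse_table_lines(
            text.splitlines(),
            name="unified_nn_dG37",
            source="SantaLucia (1998) unified nearest-neighbor ΔG°37, kcal/mol",
        )
    return _DEFAULT_TABLE


# byte-level base codes: A,C,G,T → 0..3, everything else → 255
_BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODES[ord(_b)] = _i


def encode_sequence(
    seq: str,
    table: DDSTable | None = None,
    *,
    strict: bool = True,
    sequence_id: str = "",
) -> FeatureVector:
    """Encode one sequence into its n−1 dinucleotide stability values.

    Lowercase input is uppercased before validation.  In strict mode (default)
    any non-ACGT character raises :class:`AlphabetError`; in permissive mode
    steps touching an ambiguous base are imputed with the mean of the 16 table
    values and counted in ``n_imputed``.
    """
    if table is None:
        table = default_table()
    s = seq.upper()
    if len(s) < 2:
        raise LengthError(
            f"sequence {sequence_id or '<anonymous>'!r} has length {len(s)}; need >= 2"
        )
    codes = _BASE_CODES[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    bad = codes == 255
    if bad.any():
        if strict:
            pos = int(np.flatnonzero(bad)[0])
            raise AlphabetError(
                f"sequence {sequence_id or '<anonymous>'!r}: non-ACGT character "
                f"{s[pos]!r} at position {pos + 1}"
            )
        codes = codes.copy()
        codes[bad] = 0  # placeholder; affected steps overwritten below
    idx = 4 * codes[:-1].astype(np.intp) + codes[1:].astype(np.intp)
    vals = table.lookup_array()[idx]
    n_imputed = 0
    if bad.any():
        step_bad = bad[:-1] | bad[1:]
        vals[step_bad] = table.mean_value()
        n_imputed = int(step_bad.sum())
    return FeatureVector(values=vals, sequence_id=sequence_id, n_imputed=n_imputed)


def encode_batch(
    seqs: Sequence[tuple[str, str]],
    table: DDSTable | None = None,
    *,
    strict: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Encode equal-length (id, sequence) pairs into an aligned feature matrix.

    Returns an ``(n, L−1)`` float matrix whose row *i* is
    ``encode_sequence(seqs[i])``, plus the id list in the same order.  Mixed
    sequence lengths raise :class:`ShapeError` (the classifier needs a fixed
    feature width); per-sequence encoding errors are re-raised carrying the
    offending id.
    """
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.float64), []
    lengths = {len(s) for _, s in seqs}
    if len(lengths) != 1:
        raise ShapeError(f"sequences have mixed lengths {sorted(lengths)}; all must match")
    (length,) = lengths
    if length < 2:
        raise LengthError(f"sequences of length {length}; need >= 2")
    ids = [sid for sid, _ in seqs]
    mat = np.empty((len(seqs), length - 1), dtype=np.float64)
    for i, (sid, s) in enumerate(seqs):
        mat[i] = encode_sequence(s, table, strict=strict, sequence_id=sid).values
    return mat, ids
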