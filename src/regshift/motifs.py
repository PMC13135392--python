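"""Motif models: IUPAC consensus handling, position frequency matrices, log-odds scoring.

A :class:`MotifModel` couples a position frequency matrix (PFM, JASPAR
count convention, rows A/C/G/T) with the IUPAC consensus derived from it
and a log-odds score threshold used when scanning in PWM mode.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# IUPAC code -> set of concrete bases it matches
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_BASESET_TO_IUPAC = {frozenset(v): k for k, v in IUPAC.items()}

_COMPLEMENT = str.maketrans("ACGTRYWSKMBDHVN", "TGCAYRWSMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def consensus_from_pfm(pfm: np.ndarray) -> str:
    """Max-count base per column; IUPAC ambiguity code when counts tie."""
    letters = []
    for col in pfm.T:
        top = col.max()
        tied = frozenset(BASES[i] for i in range(4) if col[i] == top)
        letters.append(_BASESET_TO_IUPAC[tied])
    return "".join(letters)


@dataclass
class MotifModel:
    """A named DNA motif with consensus, PFM and a log-odds threshold (bits)."""

    name: str
    consensus: str
    pfm: np.ndarray  # 4 x L counts, rows A,C,G,T
    min_score: float = 0.0

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape != (4, len(self.consensus)):
            raise ValueError(
                f"PFM shape {self.pfm.shape} inconsistent with consensus "
                f"length {len(self.consensus)}"
            )
        if len(self.consensus) < 4:
            raise ValueError("motif length must be >= 4")
        if np.any(self.pfm < 0):
            raise ValueError("PFM counts must be nonnegative")
        if np.any(self.pfm.sum(axis=0) <= 0):
            raise ValueError("every PFM column must have a positive sum")
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"unknown IUPAC letters in consensus: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.consensus)

    @classmethod
    def from_consensus(cls, name: str, consensus: str, min_score: float = 0.0,
                       count: float = 100.0) -> "MotifModel":
        """Build a degenerate PFM that spreads ``count`` over each column's bases."""
        consensus = consensus.upper()
        L = len(consensus)
        pfm = np.zeros((4, L))
        for j, letter in enumerate(consensus):
            try:
                bases = IUPAC[letter]
            except KeyError:
                raise ValueError(f"unknown IUPAC letter {letter!r}") from None
            for b in bases:
                pfm[BASE_INDEX[b], j] = count / len(bases)
        return cls(name=name, consensus=consensus, pfm=pfm, min_score=min_score)

    def pwm(self, background: np.ndarray | None = None,
            pseudocount: float = 0.5) -> np.ndarray:
        """Log2-odds matrix vs. a background base distribution."""
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        probs = (self.pfm + pseudocount) / (self.pfm + pseudocount).sum(axis=0)
        return np.log2(probs / background[:, None])


def matches_consensus(seq: str, consensus: str, max_mismatch: int = 0) -> bool:
    """True when ``seq`` matches the IUPAC consensus with at most ``max_mismatch`` errors."""
    if len(seq) != len(consensus):
        return False
    mismatches = 0
    for s, c in zip(seq, consensus):
        try:
            allowed = IUPAC[c]
        except KeyError:
            raise ValueError(f"unknown IUPAC letter {c!r}") from None
        if s not in allowed:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def read_jaspar_pfm(path_or_handle) -> list[MotifModel]:
    """Parse motifs from a JASPAR-format PFM file.

    Expects the 2016+ text dialect: a ``>ID name`` header followed by four
    rows ``A [ 1 2 3 ]`` ... in any base order; rows are reordered to A,C,G,T.
    """
    if hasattr(path_or_handle, "read"):
        text = path_or_handle.read()
    else:
        with open(path_or_handle) as fh:
            text = fh.read()
    motifs: list[MotifModel] = []
    header: str | None = None
    rows: dict[str, list[float]] = {}

    def _flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        missing = set(BASES) - set(rows)
        if missing:
            raise ValueError(f"motif {header!r}: missing rows for {sorted(missing)}")
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"motif {header!r}: ragged PFM columns {lengths}")
        pfm = np.array([rows[b] for b in BASES], dtype=float)
        parts = header.split(None, 1)
        motif_id = parts[0]
        name = parts[1] if len(parts) > 1 else motif_id
        motifs.append(MotifModel(name=name, consensus=consensus_from_pfm(pfm), pfm=pfm))
        header, rows = None, {}

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            header = line[1:].strip()
            continue
        base = line[0].upper()
        if base not in BASES:
            raise ValueError(f"unexpected PFM row: {line!r}")
        body = line[1:].replace("[", " ").replace("]", " ")
        try:
            values = [float(x) for x in body.split()]
        except ValueError:
            raise ValueError(f"non-numeric count in PFM row: {line!r}") from None
        if base in rows:
            raise ValueError(f"duplicate {base} row in motif {header!r}")
        rows[base] = values
    _flush()
    if not motifs:
        raise ValueError("no motifs found in JASPAR file")
    return motifs


def write_jaspar_pfm(motifs, path_or_handle) -> None:
    """Write motifs in JASPAR PFM text format (exact round-trip of counts)."""
    if isinstance(motifs, MotifModel):
        motifs = [motifs]
    lines: list[str] = []
    for m in motifs:
        lines.append(f">{m.name}")
        for i, b in enumerate(BASES):
            counts = " ".join(repr(float(v)) for v in m.pfm[i])
            lines.append(f"{b} [ {counts} ]")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)
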