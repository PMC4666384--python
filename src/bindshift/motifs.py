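"""Position weight matrices and the biophysical occupancy model.

A transcription factor's sequence preference is given as a position weight
matrix (PWM) of per-position base probabilities. For scanning, the PWM is
re-expressed as a position-specific binding energy matrix (PBEM): each base
``b`` at motif position ``j`` contributes a mismatch energy (in units of
kT), and a window ``S`` of the DNA sequence has total binding energy
``E.S`` (the sum of the per-position entries). The probability that the
site is occupied by the factor at chemical potential ``mu`` follows the
Fermi-Dirac form

    P(S) = 1 / (1 + exp(E.S - mu)).

In the low-concentration limit (``mu`` far below every window energy) this
reduces to the Maxwell-Boltzmann form ``P(S) ~ exp(-E.S)``. Total
occupancy of a sequence is the sum of ``P(S)`` over every window on both
strands.

Only the combination ``E.S - mu`` is physical, so the zero point of the
energy scale and the chemical potential are defined jointly, and two
standard anchorings are provided by :func:`pwm_to_energy`:

``consensus`` (default)
    ``E[b, j] = ln(max_b' p[b', j]) - ln(p[b, j])``: the consensus base of
    every column scores exactly 0 and mismatches are positive (the
    TRAP/BEEML convention). The per-motif offset between this scale and
    any absolute one is absorbed into ``mu``, which is what lets a single
    shared ``mu`` grid be swept across an entire heterogeneous PWM
    collection; the variant-ranking pipeline uses this anchoring.

``background``
    ``E[b, j] = -ln(p[b, j] / 0.25)``: energy relative to the uniform
    background, negative for informative consensus bases, so strong sites
    of typical motifs (width 8-20, 1-2 bits/column) land around -5 to -25.
    This fixes the gauge absolutely, which is required when ``mu`` itself
    is the quantity being estimated from occupancy data (the
    chemical-potential fit uses this anchoring).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "BASES",
    "Pwm",
    "EnergyMatrix",
    "OccupancyProfile",
    "encode_sequence",
    "reverse_complement",
    "read_pwm_collection",
    "write_jaspar",
    "pwm_to_energy",
    "window_energy",
    "binding_probability",
    "sequence_occupancy",
    "batch_window_energies",
]

log = logging.getLogger(__name__)

BASES = "ACGT"

# base -> code lookup; N (and lowercase) map to the ambiguity code 4
_CODES = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i
_CODES[ord("N")] = 4
_CODES[ord("n")] = 4

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_RC)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A,C,G,T -> 0..3, N -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODES[raw]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.flatnonzero(codes < 0)})
        raise ValueError(f"sequence contains non-DNA characters: {bad}")
    return codes


@dataclass(frozen=True)
class Pwm:
    """A position weight matrix: 4 x m base probabilities (rows A, C, G, T)."""

    id: str
    tf_name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValueError(f"PWM {self.id!r}: expected a 4 x m matrix, got {probs.shape}")
        if (probs < 0).any() or not np.isfinite(probs).all():
            raise ValueError(f"PWM {self.id!r}: probabilities must be finite and >= 0")
        sums = probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.id!r}: columns must sum to 1 (got {sums})")
        probs.flags.writeable = False
        object.__setattr__(self, "probs", probs)

    @property
    def m(self) -> int:
        """Motif width."""
        return self.probs.shape[1]

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (2 + sum p log2 p)."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + plogp.sum(axis=0)

    def consensus(self) -> str:
        """Most probable base at every position."""
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    @classmethod
    def from_counts(cls, id: str, tf_name: str, counts: np.ndarray) -> "Pwm":
        """Build a PWM from a 4 x m count (or probability) matrix, normalising columns."""
        counts = np.asarray(counts, dtype=float)
        sums = counts.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError(f"PWM {id!r}: a column has non-positive total count")
        return cls(id=id, tf_name=tf_name, probs=counts / sums)


@dataclass(frozen=True)
class EnergyMatrix:
    """Position-specific binding energies (kT units).

    The consensus base is the per-column minimum (exactly 0 under the
    ``consensus`` anchoring, negative for informative columns under
    ``background``); a uniform column scores 0 for every base in both. An
    N in a scanned window contributes the column's mean energy.
    """

    motif_id: str
    tf_name: str
    E: np.ndarray

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        if E.ndim != 2 or E.shape[0] != 4 or E.shape[1] < 1:
            raise ValueError(f"energy matrix {self.motif_id!r}: expected 4 x m, got {E.shape}")
        if not np.isfinite(E).all():
            raise ValueError(f"energy matrix {self.motif_id!r}: entries must be finite")
        E.flags.writeable = False
        object.__setattr__(self, "E", E)

    @property
    def m(self) -> int:
        return self.E.shape[1]

    def site_energy(self) -> float:
        """Energy of the best (consensus) site: sum of per-column minima."""
        return float(self.E.min(axis=0).sum())

    def extended(self) -> np.ndarray:
        """5 x m matrix with a fifth row of column means, used to score N bases."""
        return np.vstack([self.E, self.E.mean(axis=0)])


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-window binding probabilities of one motif on one sequence at one mu."""

    motif_id: str
    sequence_id: str
    mu: float
    window_probs: np.ndarray  # forward-strand windows followed by reverse-strand
    total: float


def pwm_to_energy(
    pwm: Pwm,
    pseudocount: float = 0.01,
    reference: Literal["consensus", "background"] = "consensus",
) -> EnergyMatrix:
    """Convert base probabilities to binding energies.

    Probabilities are regularised as ``p~ = (p + c) / (1 + 4c)`` with
    pseudocount ``c``; the mismatch penalty between two bases in a column
    is the log-ratio ``ln(p~_best / p~_other)`` under either anchoring, and
    a fully uninformative column scores 0 for every base. ``reference``
    selects the zero point: ``consensus`` (default) shifts every column so
    its best base scores exactly 0; ``background`` measures against the
    uniform distribution, ``E = -ln(p~ / 0.25)``, giving signed energies.
    See the module docstring for when each anchoring is appropriate.
    """
    if not 0 < pseudocount <= 0.1:
        raise ValueError(f"pseudocount must be in (0, 0.1], got {pseudocount}")
    p = (pwm.probs + pseudocount) / (1.0 + 4.0 * pseudocount)
    if reference == "consensus":
        E = np.log(p.max(axis=0)) - np.log(p)
    elif reference == "background":
        E = -np.log(4.0 * p)
    else:
        raise ValueError(f"unknown energy reference {reference!r}")
    return EnergyMatrix(motif_id=pwm.id, tf_name=pwm.tf_name, E=E)


def _rc_extended(ext: np.ndarray) -> np.ndarray:
    """Extended energy matrix that scores the reverse strand on forward codes."""
    return ext[[3, 2, 1, 0, 4], ::-1]


def batch_window_energies(energy: EnergyMatrix, codes: np.ndarray) -> np.ndarray:
    """Window energies for a batch of equal-length encoded sequences.

    Parameters
    ----------
    codes : (n, N) int array of base codes (0..3, N = 4).

    Returns
    -------
    (n, 2 * (N - m + 1)) array: forward-strand window energies followed by
    reverse-strand window energies, both in forward coordinates.
    """
    codes = np.atleast_2d(codes)
    n, N = codes.shape
    m = energy.m
    if N < m:
        raise ValueError(
            f"motif {energy.motif_id!r} (width {m}) is longer than the sequence (length {N})"
        )
    W = N - m + 1
    ext = energy.extended()
    rc = _rc_extended(ext)
    out = np.zeros((n, 2 * W))
    for j in range(m):
        block = codes[:, j : j + W]
        out[:, :W] += ext[block, j]
        out[:, W:] += rc[block, j]
    return out


def window_energy(
    energy: EnergyMatrix, sequence: str, offset: int, strand: Literal["+", "-"] = "+"
) -> float:
    """Binding energy E.S of the single window starting at ``offset`` (0-based).

    On the minus strand the reverse complement of the window is scored.
    """
    m = energy.m
    if offset < 0 or offset + m > len(sequence):
        raise ValueError(
            f"window [{offset}, {offset + m}) out of range for sequence of length {len(sequence)}"
        )
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    codes = encode_sequence(sequence[offset : offset + m])
    ext = energy.extended() if strand == "+" else _rc_extended(energy.extended())
    return float(ext[codes, np.arange(m)].sum())


def binding_probability(e, mu: float = 0.0, model: str = "fermi_dirac"):
    """Probability that a site of energy ``e`` is bound at chemical potential ``mu``.

    ``fermi_dirac``: 1 / (1 + exp(e - mu)), evaluated stably (saturates to the
    0/1 limits instead of overflowing). ``boltzmann``: exp(-e), clipped to <= 1.
    Accepts scalars or arrays.
    """
    arr = np.asarray(e, dtype=float)
    if model == "fermi_dirac":
        out = expit(mu - arr)
    elif model == "boltzmann":
        with np.errstate(over="ignore"):
            out = np.minimum(np.exp(-arr), 1.0)
    else:
        raise ValueError(f"unknown binding model {model!r}")
    return float(out) if np.isscalar(e) else out


def sequence_occupancy(
    energy: EnergyMatrix,
    sequence: str,
    mu: float = 0.0,
    model: str = "fermi_dirac",
    sequence_id: str = "",
) -> OccupancyProfile:
    """Total occupancy of a sequence: sum of window binding probabilities.

    Windows are enumerated on both strands, ``2 * (N - m + 1)`` in total.
    """
    if len(sequence) < energy.m:
        raise ValueError(
            f"sequence {sequence_id!r} (length {len(sequence)}) is shorter than "
            f"motif {energy.motif_id!r} (width {energy.m})"
        )
    ew = batch_window_energies(energy, encode_sequence(sequence))[0]
    probs = binding_probability(ew, mu, model)
    return OccupancyProfile(
        motif_id=energy.motif_id,
        sequence_id=sequence_id,
        mu=mu,
        window_probs=probs,
        total=float(probs.sum()),
    )


# ---------------------------------------------------------------------------
# PWM collection I/O


def _parse_jaspar_file(path: Path) -> list[Pwm]:
    from Bio import motifs as bio_motifs

    with open(path) as handle:
        records = list(bio_motifs.parse(handle, "jaspar"))
    out = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in BASES], dtype=float)
        mid = getattr(rec, "matrix_id", None) or path.stem
        name = rec.name or mid
        out.append(Pwm.from_counts(id=str(mid), tf_name=str(name), counts=counts))
    return out


def _parse_plain_file(path: Path) -> list[Pwm]:
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ValueError("file is empty")
    header_tokens: list[str] = []
    first = lines[0].lstrip(">").split()
    try:
        [float(tok) for tok in lines[0].split()]
    except ValueError:
        header_tokens = first
        lines = lines[1:]
    rows = []
    for ln in lines:
        try:
            rows.append([float(tok) for tok in ln.split()])
        except ValueError as exc:
            raise ValueError(f"non-numeric matrix row {ln!r}") from exc
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError("ragged matrix rows")
    mat = np.array(rows, dtype=float)
    if mat.shape[0] != 4:
        if mat.shape[1] == 4:
            mat = mat.T  # stored one position per row
        else:
            raise ValueError(f"expected a 4-row or 4-column matrix, got shape {mat.shape}")
    mid = header_tokens[0] if header_tokens else path.stem
    name = header_tokens[1] if len(header_tokens) > 1 else Path(mid).stem
    return [Pwm.from_counts(id=mid, tf_name=name, counts=mat)]


def read_pwm_collection(
    path, format: Literal["jaspar", "plain", None] = None
) -> list[Pwm]:
    """Read a PWM collection from one file or a directory of files.

    JASPAR-style text (``>id name`` headers, labelled base rows) and plain
    whitespace-delimited 4 x m (or m x 4) matrices are supported; the format
    is auto-detected per file unless ``format`` is given. Count matrices are
    normalised to probabilities column-wise. Duplicate motif ids get a
    numeric suffix; the TF name defaults to the id / file stem.
    """
    root = Path(path)
    if not root.exists():
        raise FileNotFoundError(f"PWM path does not exist: {root}")
    files = sorted(p for p in root.iterdir() if p.is_file()) if root.is_dir() else [root]
    pwms: list[Pwm] = []
    for f in files:
        text = f.read_text()
        stripped = text.lstrip()
        fmt = format or ("jaspar" if stripped.startswith(">") and any(
            ln.strip()[:1] in "ACGT" for ln in stripped.splitlines()[1:2]
        ) else "plain")
        try:
            pwms.extend(_parse_jaspar_file(f) if fmt == "jaspar" else _parse_plain_file(f))
        except Exception as exc:
            raise ValueError(f"failed to parse PWM file {f}: {exc}") from exc
    if not pwms:
        raise ValueError(f"no PWMs found under {root}")
    seen: dict[str, int] = {}
    unique: list[Pwm] = []
    for p in pwms:
        if p.id in seen:
            seen[p.id] += 1
            unique.append(Pwm(id=f"{p.id}.{seen[p.id]}", tf_name=p.tf_name, probs=p.probs))
        else:
            seen[p.id] = 0
            unique.append(p)
    return unique


def write_jaspar(path, pwms: Iterable[Pwm], counts_scale: float = 100.0) -> None:
    """Write PWMs as JASPAR-style count matrices (probabilities x counts_scale)."""
    with open(path, "w") as out:
        for p in pwms:
            out.write(f">{p.id} {p.tf_name}\n")
            for b, row in zip(BASES, p.probs * counts_scale):
                cells = " ".join(f"{v:.4f}" for v in row)
                out.write(f"{b} [ {cells} ]\n")
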