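"""Specificity profiles: PSFM construction, comparison and p-values.

A position-specific frequency matrix (PSFM) summarizes the residue
preferences of the lowest-energy fraction of a scored sequence pool.  Each
selected peptide contributes symbols at the *structural* positions through
its chosen register; positions the register leaves uncovered are counted as
the placeholder symbol 'X'.  PSFMs are compared by Frobenius distance
(square root of the summed squared frequency differences), and a profile's
significance against a reference PWM is the lower tail of a normal fit to
the null distribution of distances between the reference and profiles built
from uniform-random sequence sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .matrixio import AA_INDEX, AMINO_ACIDS, N_POSITIONS, _check_sequence
from .ensemble import BindingPrediction
from .scoring import map_sequence

PSFM_SYMBOLS = AMINO_ACIDS + "X"
X_INDEX = len(AMINO_ACIDS)
P_VALUE_FLOOR = 1e-100

#: canonical motif letters fixed by the motif sequence generators,
#: 0-based offsets from the anchor
_MOTIF_LETTERS = {
    "I": ((0, "R"), (3, "P"), (6, "P")),
    "II": ((0, "P"), (3, "P"), (5, "R")),
}
MOTIF_SPAN = {"I": 7, "II": 6}


class PSFMError(ValueError):
    """Raised on invalid profile construction or comparison."""


@dataclass
class PSFM:
    """Column-normalized frequency matrix over 20 residues + 'X'.

    ``freqs`` has shape ``(21, width)``; rows follow ``PSFM_SYMBOLS``.
    """

    freqs: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.ndim != 2 or self.freqs.shape[0] != len(PSFM_SYMBOLS):
            raise PSFMError(
                f"freqs must have {len(PSFM_SYMBOLS)} symbol rows, "
                f"got shape {self.freqs.shape}"
            )
        if np.any(self.freqs < -1e-12):
            raise PSFMError("frequencies must be non-negative")
        sums = self.freqs.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise PSFMError(
                f"column {bad + 1} frequencies sum to {sums[bad]!r}, expected 1"
            )

    @property
    def width(self) -> int:
        return self.freqs.shape[1]

    def frequency(self, symbol: str, position: int) -> float:
        return float(self.freqs[PSFM_SYMBOLS.index(symbol), position - 1])

    def consensus(self) -> str:
        return "".join(PSFM_SYMBOLS[i] for i in self.freqs.argmax(axis=0))


@dataclass
class SequenceSetSpec:
    """Recipe for an evaluation sequence set.

    ``uniform`` draws residues i.i.d. with equal probability; the motif
    modes fix the literal letters RxxPxxP (class I) or PxxPxR (class II) at
    ``anchor`` (1-based, default 1) and draw the other sites uniformly;
    ``from_psfm`` samples positions independently from the reference PSFM
    columns with any 'X' mass renormalized away.
    """

    mode: str
    n: int
    length: int = N_POSITIONS
    seed: Optional[int] = None
    reference_psfm: Optional[PSFM] = None
    anchor: int = 1
    charged: str = "R"

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "motif_classI", "motif_classII", "from_psfm"):
            raise ValueError(f"unknown sequence mode {self.mode!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.mode == "from_psfm" and self.reference_psfm is None:
            raise ValueError("from_psfm mode requires reference_psfm")
        if self.charged not in ("R", "K"):
            raise ValueError("charged motif residue must be 'R' or 'K'")
        if self.mode.startswith("motif_class"):
            cls = self.mode.removeprefix("motif_class")
            if self.anchor < 1 or self.anchor + MOTIF_SPAN[cls] - 1 > self.length:
                raise ValueError(
                    f"class {cls} motif (span {MOTIF_SPAN[cls]}) does not fit "
                    f"length {self.length} at anchor {self.anchor}"
                )


def generate_sequences(spec: SequenceSetSpec) -> list[str]:
    """Seeded, reproducible sequence generation per ``spec``."""
    rng = np.random.default_rng(spec.seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    if spec.mode == "from_psfm":
        psfm = spec.reference_psfm
        assert psfm is not None
        if spec.length != psfm.width:
            raise ValueError(
                f"length {spec.length} != reference PSFM width {psfm.width}"
            )
        cols = []
        for pos in range(psfm.width):
            probs = psfm.freqs[:X_INDEX, pos].copy()
            total = probs.sum()
            if total <= 0:
                raise PSFMError(
                    f"PSFM column {pos + 1} has all mass on 'X'; cannot sample"
                )
            cols.append(rng.choice(20, size=spec.n, p=probs / total))
        codes = np.stack(cols, axis=1)
    else:
        codes = rng.integers(0, 20, size=(spec.n, spec.length))
    seqs = ["".join(AMINO_ACIDS[c] for c in row) for row in codes]
    if spec.mode.startswith("motif_class"):
        cls = spec.mode.removeprefix("motif_class")
        fixed = list(_MOTIF_LETTERS[cls])
        out = []
        for s in seqs:
            chars = list(s)
            for delta, letter in fixed:
                chars[spec.anchor - 1 + delta] = (
                    spec.charged if letter == "R" else letter
                )
            out.append("".join(chars))
        seqs = out
    return seqs


def psfm_from_sequences(
    sequences: Sequence[str], width: int = N_POSITIONS
) -> PSFM:
    """PSFM of raw equal-register sequences (offset 0, no 'X' except padding)."""
    if not sequences:
        raise PSFMError("cannot build a PSFM from an empty sequence set")
    counts = np.zeros((len(PSFM_SYMBOLS), width))
    for s in sequences:
        _check_sequence(s)
        for pos in range(width):
            idx = AA_INDEX[s[pos]] if pos < len(s) else X_INDEX
            counts[idx, pos] += 1
    return PSFM(freqs=counts / len(sequences), n_sequences=len(sequences))


def build_psfm(predictions: Sequence[BindingPrediction], top_k: int) -> PSFM:
    """Frequency profile of the ``top_k`` lowest-energy predictions.

    Symbols are placed at structural positions through each peptide's chosen
    register; uncovered positions count as 'X'.  Ties at the energy cutoff
    are broken by input order.
    """
    if not predictions:
        raise PSFMError("cannot build a PSFM from an empty prediction list")
    if not 1 <= top_k <= len(predictions):
        raise PSFMError(
            f"top_k must be in 1..{len(predictions)}, got {top_k}"
        )
    energies = np.array([p.energy for p in predictions])
    order = np.argsort(energies, kind="stable")[:top_k]
    counts = np.zeros((len(PSFM_SYMBOLS), N_POSITIONS))
    for idx in order:
        p = predictions[idx]
        mapping = map_sequence(p.peptide, p.offset)
        for pos, residue in enumerate(mapping.residues):
            row = AA_INDEX[residue] if residue is not None else X_INDEX
            counts[row, pos] += 1
    return PSFM(freqs=counts / top_k, n_sequences=top_k)


def frobenius_distance(a: PSFM, b: PSFM, include_x: bool = False) -> float:
    """Square root of the summed squared elementwise frequency differences.

    The 'X' row is excluded by default because reference PWMs carry no
    placeholder mass; pass ``include_x=True`` to compare all 21 rows.
    """
    if a.width != b.width:
        raise PSFMError(
            f"width mismatch: {a.width} vs {b.width} (no implicit sliding; "
            "use best_shift_distance for register-shifted comparison)"
        )
    rows = slice(None) if include_x else slice(0, X_INDEX)
    diff = a.freqs[rows] - b.freqs[rows]
    return float(np.sqrt((diff * diff).sum()))


def best_shift_distance(
    a: PSFM, b: PSFM, max_shift: int = 4, include_x: bool = False
) -> tuple[int, float]:
    """Minimum Frobenius distance over column shifts of ``b`` against ``a``.

    Shift s compares a's columns i with b's columns i - s on the overlap
    only (raw distance over the overlapping columns, not normalized), so
    distances at different shifts weigh different numbers of columns.  Ties
    prefer |shift| small, then negative.
    """
    rows = slice(None) if include_x else slice(0, X_INDEX)
    best: Optional[tuple[int, float]] = None
    for s in sorted(range(-max_shift, max_shift + 1), key=lambda x: (abs(x), x)):
        lo_a, hi_a = max(0, s), min(a.width, b.width + s)
        if hi_a <= lo_a:
            continue
        diff = a.freqs[rows, lo_a:hi_a] - b.freqs[rows, lo_a - s : hi_a - s]
        d = float(np.sqrt((diff * diff).sum()))
        if best is None or d < best[1]:
            best = (s, d)
    if best is None:
        raise PSFMError("no overlapping columns within the shift range")
    return best


@dataclass
class PValueResult:
    distance: float
    null_mean: float
    null_sd: float
    n_null: int
    p: float


def psfm_pvalue(
    observed: PSFM,
    reference: PSFM,
    n_null: int = 1000,
    set_size: Optional[int] = None,
    seed: Optional[int] = None,
    null: str = "uniform_sequences",
    full_output: bool = False,
):
    """Lower-tail p-value of the observed-vs-reference Frobenius distance.

    The null distribution is the Frobenius distance between the reference
    and profiles of ``n_null`` independent uniform-random sequence sets of
    ``set_size`` sequences (default: the observed profile's own set size).
    A normal distribution is fitted to the null distances so that extreme
    profiles can be assigned p-values far below 1/n_null; the result is
    floored at 1e-100.  ``null="dirichlet"`` instead draws each null column
    from a flat Dirichlet over the 20 residues.
    """
    if observed.width != reference.width:
        raise PSFMError(
            f"width mismatch: {observed.width} vs {reference.width}"
        )
    if n_null < 100:
        raise ValueError("n_null must be >= 100 for a stable normal fit")
    if set_size is None:
        set_size = observed.n_sequences
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    rng = np.random.default_rng(seed)
    distances = np.empty(n_null)
    for k in range(n_null):
        if null == "uniform_sequences":
            codes = rng.integers(0, 20, size=(set_size, reference.width))
            counts = np.zeros((len(PSFM_SYMBOLS), reference.width))
            for pos in range(reference.width):
                np.add.at(counts[:, pos], codes[:, pos], 1.0)
            null_psfm = PSFM(freqs=counts / set_size, n_sequences=set_size)
        elif null == "dirichlet":
            freqs = np.zeros((len(PSFM_SYMBOLS), reference.width))
            freqs[:X_INDEX] = rng.dirichlet(np.ones(20), size=reference.width).T
            null_psfm = PSFM(freqs=freqs, n_sequences=set_size)
        else:
            raise ValueError(f"unknown null model {null!r}")
        distances[k] = frobenius_distance(null_psfm, reference)
    mu = float(distances.mean())
    sd = float(distances.std(ddof=1))
    if sd == 0.0:
        raise PSFMError("null distance distribution has zero variance")
    d_obs = frobenius_distance(observed, reference)
    p = float(stats.norm.cdf(d_obs, loc=mu, scale=sd))
    p = min(1.0, max(p, P_VALUE_FLOOR))
    if full_output:
        return PValueResult(distance=d_obs, null_mean=mu, null_sd=sd,
                            n_null=n_null, p=p)
    return p


def write_psfm(psfm: PSFM, path: str | Path, format: str = "tsv") -> None:
    """Serialize a profile: lossless ``tsv`` or logo-tool ``transfac`` counts."""
    path = Path(path)
    if format == "tsv":
        lines = ["pos\t" + "\t".join(PSFM_SYMBOLS)]
        for pos in range(psfm.width):
            cells = "\t".join(f"{v:.12g}" for v in psfm.freqs[:, pos])
            lines.append(f"{pos + 1}\t{cells}")
        lines.append(f"#n_sequences={psfm.n_sequences}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "transfac":
        lines = [
            "ID synthetic_psfm",
            "BF synthetic",
            "PO\t" + "\t".join(PSFM_SYMBOLS),
        ]
        for pos in range(psfm.width):
            counts = np.rint(psfm.freqs[:, pos] * psfm.n_sequences).astype(int)
            lines.append(f"{pos + 1:02d}\t" + "\t".join(str(c) for c in counts))
        lines.append("XX")
        lines.append("//")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown PSFM format {format!r}")


def read_psfm(path: str | Path) -> PSFM:
    """Read the ``tsv`` PSFM format, validating column normalization."""
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise PSFMError(f"{path}: empty file")
    n_sequences = 0
    header = lines[0].split("\t")
    if header != ["pos"] + list(PSFM_SYMBOLS):
        raise PSFMError(f"{path}:1: unexpected header {lines[0]!r}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if key == "n_sequences":
                n_sequences = int(value)
            continue
        fields = line.split("\t")
        if len(fields) != len(PSFM_SYMBOLS) + 1:
            raise PSFMError(
                f"{path}:{lineno}: expected {len(PSFM_SYMBOLS) + 1} columns"
            )
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError:
            raise PSFMError(f"{path}:{lineno}: non-numeric frequency") from None
    freqs = np.array(rows).T
    try:
        return PSFM(freqs=freqs, n_sequences=n_sequences)
    except PSFMError as exc:
        raise PSFMError(f"{path}: {exc}") from None
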