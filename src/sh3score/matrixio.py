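"""Energy-matrix, ensemble and SPOT-table containers and their text formats.

An *energy matrix* tabulates the binding-energy contribution of each of the
20 canonical amino acids at each of the 10 structural positions of a peptide
bound to an SH3 domain, for one (peptide template, conformation) pair.
Energies are in FoldX-style arbitrary units: lower means tighter binding.
A *matrix ensemble* is the complete templates x conformations grid for one
domain.  SPOT-array intensities (BLU) are carried alongside a pseudo-energy
obtained by ``-ln(blu + pseudocount)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_POSITIONS = 10
TEMPLATE_CLASSES = ("I", "II")
DEFAULT_UNIT = "kcal/mol-like (FoldX)"

#: suffix used for energy-matrix files inside an ensemble directory
MATRIX_SUFFIX = ".em.tsv"


class MatrixFormatError(ValueError):
    """Raised when an energy-matrix file violates the format contract."""


class EnsembleError(ValueError):
    """Raised when a template x conformation grid is inconsistent."""


class SpotFormatError(ValueError):
    """Raised when a SPOT table file violates the format contract."""


def _check_sequence(peptide: str, where: str = "peptide") -> None:
    if not peptide:
        raise ValueError(f"{where} must be a non-empty string")
    bad = set(peptide) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(
            f"{where} {peptide!r} contains non-canonical characters: "
            f"{''.join(sorted(bad))}"
        )


@dataclass
class EnergyMatrix:
    """Per-position amino-acid binding-energy contributions for one conformation.

    ``values`` is a ``(20, 10)`` float array; rows follow the alphabetical
    one-letter residue order ``ACDEFGHIKLMNPQRSTVWY`` and columns are the
    structural positions 1..10.
    """

    domain_id: str
    template_id: int
    template_class: str
    conformation_id: int
    values: np.ndarray
    unit: str = DEFAULT_UNIT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(AMINO_ACIDS), N_POSITIONS):
            raise MatrixFormatError(
                f"energy matrix must be {len(AMINO_ACIDS)}x{N_POSITIONS}, "
                f"got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise MatrixFormatError("energy matrix contains non-finite entries")
        if self.template_class not in TEMPLATE_CLASSES:
            raise MatrixFormatError(
                f"template_class must be one of {TEMPLATE_CLASSES}, "
                f"got {self.template_class!r}"
            )
        self.template_id = int(self.template_id)
        self.conformation_id = int(self.conformation_id)

    def energy(self, residue: str, position: int) -> float:
        """Energy contribution of ``residue`` at 1-based structural ``position``."""
        if residue not in AA_INDEX:
            raise KeyError(f"unknown residue {residue!r}")
        if not 1 <= position <= N_POSITIONS:
            raise IndexError(f"position must be in 1..{N_POSITIONS}, got {position}")
        return float(self.values[AA_INDEX[residue], position - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=list(AMINO_ACIDS),
            columns=[f"P{i}" for i in range(1, N_POSITIONS + 1)],
        )


def write_energy_matrix(matrix: EnergyMatrix, path: str | Path) -> None:
    """Write ``matrix`` in the metadata-header TSV dialect (full precision)."""
    path = Path(path)
    lines = [
        f"#domain_id={matrix.domain_id}",
        f"#template_id={matrix.template_id}",
        f"#template_class={matrix.template_class}",
        f"#conformation_id={matrix.conformation_id}",
        f"#unit={matrix.unit}",
        "AA\t" + "\t".join(f"P{i}" for i in range(1, N_POSITIONS + 1)),
    ]
    for r, aa in enumerate(AMINO_ACIDS):
        cells = "\t".join(repr(float(v)) for v in matrix.values[r])
        lines.append(f"{aa}\t{cells}")
    path.write_text("\n".join(lines) + "\n")


def read_energy_matrix(path: str | Path) -> EnergyMatrix:
    """Parse an energy-matrix TSV file, validating the 20 x 10 contract."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: dict[str, np.ndarray] = {}
    header_seen = False
    expected_header = ["AA"] + [f"P{i}" for i in range(1, N_POSITIONS + 1)]
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if not header_seen:
            if fields != expected_header:
                header_repr = "\t".join(expected_header)
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected header "
                    f"{header_repr!r}, got {line!r}"
                )
            header_seen = True
            continue
        aa = fields[0]
        if aa not in AA_INDEX:
            raise MatrixFormatError(f"{path}:{lineno}: unknown residue row {aa!r}")
        if aa in rows:
            raise MatrixFormatError(f"{path}:{lineno}: duplicate residue row {aa!r}")
        if len(fields) != N_POSITIONS + 1:
            raise MatrixFormatError(
                f"{path}:{lineno}: residue row {aa!r} has {len(fields) - 1} "
                f"value columns, expected {N_POSITIONS}"
            )
        values = np.empty(N_POSITIONS)
        for c, cell in enumerate(fields[1:], start=1):
            try:
                values[c - 1] = float(cell)
            except ValueError:
                raise MatrixFormatError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} at residue "
                    f"{aa}, position P{c}"
                ) from None
        rows[aa] = values
    if not header_seen:
        raise MatrixFormatError(f"{path}: missing header line")
    missing = [aa for aa in AMINO_ACIDS if aa not in rows]
    if missing:
        raise MatrixFormatError(
            f"{path}: missing residue rows: {', '.join(missing)}"
        )
    required = ("domain_id", "template_id", "template_class", "conformation_id")
    for key in required:
        if key not in meta:
            raise MatrixFormatError(f"{path}: missing metadata field #{key}=")
    values = np.vstack([rows[aa] for aa in AMINO_ACIDS])
    return EnergyMatrix(
        domain_id=meta["domain_id"],
        template_id=int(meta["template_id"]),
        template_class=meta["template_class"],
        conformation_id=int(meta["conformation_id"]),
        values=values,
        unit=meta.get("unit", DEFAULT_UNIT),
    )


@dataclass
class MatrixEnsemble:
    """Complete (template, conformation) grid of energy matrices for one domain."""

    domain_id: str
    matrices: dict[tuple[int, int], EnergyMatrix]
    class_of: dict[int, str] = field(default_factory=dict)
    _array_cache: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.matrices:
            raise EnsembleError("ensemble must contain at least one matrix")
        if not self.class_of:
            self.class_of = {
                t: m.template_class
                for (t, _), m in sorted(self.matrices.items())
            }
        t_ids = sorted({t for t, _ in self.matrices})
        c_ids = sorted({c for _, c in self.matrices})
        missing = [(t, c) for t in t_ids for c in c_ids if (t, c) not in self.matrices]
        if missing:
            raise EnsembleError(
                "incomplete template x conformation grid; missing pairs: "
                + ", ".join(f"(template {t}, conformation {c})" for t, c in missing)
            )
        for (t, c), m in self.matrices.items():
            if m.domain_id != self.domain_id:
                raise EnsembleError(
                    f"matrix (template {t}, conformation {c}) has domain_id "
                    f"{m.domain_id!r}, expected {self.domain_id!r}"
                )
            if self.class_of.get(t) != m.template_class:
                raise EnsembleError(
                    f"template {t} has conflicting class labels: "
                    f"{self.class_of.get(t)!r} vs {m.template_class!r}"
                )
        for t in t_ids:
            if self.class_of[t] not in TEMPLATE_CLASSES:
                raise EnsembleError(f"template {t} has invalid class {self.class_of[t]!r}")

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def template_ids(self) -> list[int]:
        return sorted({t for t, _ in self.matrices})

    @property
    def conformation_ids(self) -> list[int]:
        return sorted({c for _, c in self.matrices})

    @property
    def n_templates(self) -> int:
        return len(self.template_ids)

    @property
    def n_conformations(self) -> int:
        return len(self.conformation_ids)

    def templates_of_class(self, template_class: str) -> list[int]:
        return [t for t in self.template_ids if self.class_of[t] == template_class]

    def as_array(self) -> tuple[np.ndarray, list[int], list[int]]:
        """Stacked view ``(E, template_ids, conformation_ids)``.

        ``E`` has shape ``(n_templates, n_conformations, 20, 10)`` with axes
        ordered by ascending template / conformation id.
        """
        if self._array_cache is None:
            t_ids = self.template_ids
            c_ids = self.conformation_ids
            arr = np.empty((len(t_ids), len(c_ids), len(AMINO_ACIDS), N_POSITIONS))
            for ti, t in enumerate(t_ids):
                for ci, c in enumerate(c_ids):
                    arr[ti, ci] = self.matrices[(t, c)].values
            self._array_cache = (arr, t_ids, c_ids)
        return self._array_cache


def write_ensemble(ensemble: MatrixEnsemble, directory: str | Path) -> Path:
    """Write every matrix plus a ``manifest.tsv`` into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_lines = ["template_id\tclass\tconformation_id\tfile"]
    for (t, c) in sorted(ensemble.matrices):
        fname = f"{ensemble.domain_id}_t{t:02d}_c{c:02d}{MATRIX_SUFFIX}"
        write_energy_matrix(ensemble.matrices[(t, c)], directory / fname)
        manifest_lines.append(f"{t}\t{ensemble.class_of[t]}\t{c}\t{fname}")
    (directory / "manifest.tsv").write_text("\n".join(manifest_lines) + "\n")
    return directory


def load_ensemble(
    directory: str | Path, manifest: str | Path | None = None
) -> MatrixEnsemble:
    """Load a complete matrix grid from ``directory``.

    If ``manifest`` is not given, ``directory/manifest.tsv`` is used when
    present; otherwise every ``*.em.tsv`` file in the directory is read.
    """
    directory = Path(directory)
    if manifest is None and (directory / "manifest.tsv").exists():
        manifest = directory / "manifest.tsv"
    files: list[Path]
    if manifest is not None:
        manifest = Path(manifest)
        files = []
        lines = manifest.read_text().splitlines()
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("template_id"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise EnsembleError(
                    f"{manifest}:{lineno}: expected 4 tab-separated fields"
                )
            files.append(directory / fields[3])
    else:
        files = sorted(directory.glob(f"*{MATRIX_SUFFIX}"))
    if not files:
        raise EnsembleError(f"no energy-matrix files found in {directory}")
    matrices: dict[tuple[int, int], EnergyMatrix] = {}
    domain_ids = set()
    for f in files:
        m = read_energy_matrix(f)
        key = (m.template_id, m.conformation_id)
        if key in matrices:
            raise EnsembleError(
                f"duplicate matrix for template {m.template_id}, "
                f"conformation {m.conformation_id} ({f})"
            )
        matrices[key] = m
        domain_ids.add(m.domain_id)
    if len(domain_ids) > 1:
        raise EnsembleError(
            f"conflicting domain_id values in {directory}: {sorted(domain_ids)}"
        )
    return MatrixEnsemble(domain_id=domain_ids.pop(), matrices=matrices)


def blu_to_energy(blu, pseudocount: float = 1.0):
    """Convert SPOT BLU intensity to pseudo-energy ``-ln(blu + pseudocount)``.

    The bound-complex count is taken as proportional to BLU, so the energy is
    the negative log intensity; the pseudocount keeps the transform defined at
    zero intensity (default 1.0, giving E(0) = 0).  Strictly decreasing in blu.
    Accepts scalars or arrays.
    """
    blu_arr = np.asarray(blu, dtype=np.float64)
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    if np.any(blu_arr < 0):
        raise ValueError("blu values must be non-negative")
    if np.any(blu_arr + pseudocount <= 0):
        raise ValueError(
            "blu + pseudocount must be positive (zero BLU requires a "
            "positive pseudocount)"
        )
    energy = -np.log(blu_arr + pseudocount)
    return float(energy) if np.isscalar(blu) or energy.ndim == 0 else energy


@dataclass
class SpotTable:
    """SPOT-array rows: peptide, BLU intensity, derived pseudo-energy."""

    frame: pd.DataFrame
    pseudocount: float = 1.0

    @classmethod
    def from_pairs(
        cls,
        peptides: Sequence[str],
        blus: Sequence[float],
        pseudocount: float = 1.0,
    ) -> "SpotTable":
        if len(peptides) != len(blus):
            raise ValueError("peptides and blus must have equal length")
        for p in peptides:
            _check_sequence(p)
        blu_arr = np.asarray(blus, dtype=np.float64)
        if len(blu_arr) and np.any(blu_arr < 0):
            raise ValueError("BLU values must be non-negative")
        energy = blu_to_energy(blu_arr, pseudocount) if len(blu_arr) else blu_arr
        frame = pd.DataFrame(
            {"peptide": list(peptides), "blu": blu_arr, "energy": energy}
        )
        return cls(frame=frame, pseudocount=pseudocount)

    @property
    def peptides(self) -> list[str]:
        return list(self.frame["peptide"])

    @property
    def blu(self) -> np.ndarray:
        return self.frame["blu"].to_numpy()

    @property
    def energy(self) -> np.ndarray:
        return self.frame["energy"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


def read_spot_table(path: str | Path, pseudocount: float = 1.0) -> SpotTable:
    """Read a ``peptide<TAB>blu`` TSV; energies are attached on load."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise SpotFormatError(f"{path}: empty file (expected a header line)")
    header = lines[0].split("\t")
    if header[:2] != ["peptide", "blu"]:
        raise SpotFormatError(
            f"{path}:1: expected header 'peptide\\tblu', got {lines[0]!r}"
        )
    peptides: list[str] = []
    blus: list[float] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise SpotFormatError(f"{path}:{lineno}: expected 2 columns")
        pep = fields[0]
        try:
            _check_sequence(pep)
        except ValueError as exc:
            raise SpotFormatError(f"{path}:{lineno}: {exc}") from None
        try:
            blu = float(fields[1])
        except ValueError:
            raise SpotFormatError(
                f"{path}:{lineno}: non-numeric BLU value {fields[1]!r}"
            ) from None
        peptides.append(pep)
        blus.append(blu)
    return SpotTable.from_pairs(peptides, blus, pseudocount=pseudocount)


def write_spot_table(table: SpotTable, path: str | Path) -> None:
    """Write the peptide/blu columns (full precision; energies are derived)."""
    path = Path(path)
    lines = ["peptide\tblu"]
    for pep, blu in zip(table.frame["peptide"], table.frame["blu"]):
        lines.append(f"{pep}\t{repr(float(blu))}")
    path.write_text("\n".join(lines) + "\n")


def read_peptides(path: str | Path) -> list[str]:
    """Read peptides from a one-per-line text file or a FASTA file."""
    path = Path(path)
    text = path.read_text()
    peptides: list[str] = []
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        for record in SeqIO.parse(str(path), "fasta"):
            peptides.append(str(record.seq).upper())
    else:
        peptides = [line.strip().upper() for line in text.splitlines() if line.strip()]
    for p in peptides:
        _check_sequence(p)
    return peptides
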