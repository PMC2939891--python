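"""Synthetic fixtures shaped like an MD + positional-mutagenesis pipeline.

Real matrix ensembles come from a molecular-dynamics trajectory of each
domain-peptide complex (conformations sampled on a uniform time grid) fed
through positional mutagenesis energy calculations.  This module emulates
that output directly at the energy-matrix level:

* a per-class *ground-truth* 20 x 10 matrix with favorable energies at the
  canonical motif cells (class I (R/K)xxPxxP, class II PxxPx(R/K)) on a
  Gaussian background;
* templates = class truth + a fixed per-template Gaussian perturbation,
  conformations = template + per-snapshot Gaussian noise, giving the full
  templates x conformations grid (default 9 x 11 = 99 matrices, split
  3 class I / 6 class II);
* SPOT tables whose BLU intensities are ``exp(-E_true)`` times
  multiplicative log-normal noise, so the log conversion recovers the true
  energy plus additive Gaussian noise.

Noise is applied to matrix entries, not structures: the simplest model of
an energy calculation that is sensitive to small structural variation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .matrixio import (
    AA_INDEX,
    AMINO_ACIDS,
    N_POSITIONS,
    EnergyMatrix,
    MatrixEnsemble,
    SpotTable,
    write_ensemble,
    write_spot_table,
)
from .scoring import map_sequence
from .specificity import MOTIF_SPAN, SequenceSetSpec, generate_sequences

#: (residue, 0-based delta from anchor) cells set to the favorable energy
_MOTIF_CELLS = {
    "I": (("R", 0), ("K", 0), ("P", 3), ("P", 6)),
    "II": (("P", 0), ("P", 3), ("R", 5), ("K", 5)),
}


@dataclass
class TruthSpec:
    """Ground-truth generator settings (energies in FoldX-like units)."""

    seed: int = 0
    n_templates: int = 9
    class_split: tuple[int, int] = (3, 6)
    n_conformations: int = 11
    motif_anchor: dict[str, int] = field(default_factory=lambda: {"I": 3, "II": 3})
    favorable_energy: float = -2.0
    background_sd: float = 0.5
    conformation_sd: float = 0.3
    template_sd: float = 0.4
    domain_id: str = "synthetic"

    def __post_init__(self) -> None:
        if sum(self.class_split) != self.n_templates:
            raise ValueError(
                f"class_split {self.class_split} must sum to "
                f"n_templates {self.n_templates}"
            )
        if min(self.background_sd, self.conformation_sd, self.template_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_conformations < 1 or self.n_templates < 1:
            raise ValueError("need at least one template and one conformation")
        for cls, anchor in self.motif_anchor.items():
            if anchor < 1 or anchor + MOTIF_SPAN[cls] - 1 > N_POSITIONS:
                raise ValueError(
                    f"class {cls} motif (span {MOTIF_SPAN[cls]}) does not fit "
                    f"the {N_POSITIONS} positions at anchor {anchor}"
                )


@dataclass
class SpotNoiseSpec:
    """SPOT-table generator settings: multiplicative log-normal BLU noise."""

    seed: int = 0
    n_peptides: int = 500
    length: int = N_POSITIONS
    lognormal_sd: float = 0.2
    composition: str = "motif_classII"
    anchor: int = 3

    def __post_init__(self) -> None:
        if self.lognormal_sd < 0:
            raise ValueError("lognormal_sd must be >= 0")


def simulate_truth(spec: TruthSpec) -> tuple[dict[str, np.ndarray], dict]:
    """Per-class ground-truth matrices with motif cells set to the favorable energy.

    Background entries are N(0, background_sd^2); the motif cells (both R and
    K at the charged site) are overwritten with ``favorable_energy``.
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed, 0])
    truth: dict[str, np.ndarray] = {}
    for cls in ("I", "II"):
        m = rng.normal(0.0, spec.background_sd, size=(len(AMINO_ACIDS), N_POSITIONS))
        anchor = spec.motif_anchor[cls]
        for residue, delta in _MOTIF_CELLS[cls]:
            m[AA_INDEX[residue], anchor - 1 + delta] = spec.favorable_energy
        truth[cls] = m
    meta = {
        "seed": spec.seed,
        "motif_anchor": dict(spec.motif_anchor),
        "favorable_energy": spec.favorable_energy,
        "background_sd": spec.background_sd,
        "motif_cells": {
            cls: [[r, spec.motif_anchor[cls] + d] for r, d in cells]
            for cls, cells in _MOTIF_CELLS.items()
        },
    }
    return truth, meta


def template_classes(spec: TruthSpec) -> dict[int, str]:
    """Class label per template id: the first ``class_split[0]`` are class I."""
    n_i = spec.class_split[0]
    return {
        t: ("I" if t <= n_i else "II") for t in range(1, spec.n_templates + 1)
    }


def simulate_ensemble(
    truth: dict[str, np.ndarray], spec: TruthSpec
) -> MatrixEnsemble:
    """Noisy template x conformation grid around the class truths.

    Template t carries a fixed N(0, template_sd^2) per-entry perturbation of
    its class truth; each conformation adds independent
    N(0, conformation_sd^2) per-entry noise on top.
    """
    rng = np.random.default_rng([spec.seed, 1])
    classes = template_classes(spec)
    matrices: dict[tuple[int, int], EnergyMatrix] = {}
    shape = (len(AMINO_ACIDS), N_POSITIONS)
    for t in range(1, spec.n_templates + 1):
        cls = classes[t]
        base = truth[cls] + rng.normal(0.0, spec.template_sd, size=shape)
        for c in range(1, spec.n_conformations + 1):
            values = base + rng.normal(0.0, spec.conformation_sd, size=shape)
            matrices[(t, c)] = EnergyMatrix(
                domain_id=spec.domain_id,
                template_id=t,
                template_class=cls,
                conformation_id=c,
                values=values,
            )
    return MatrixEnsemble(domain_id=spec.domain_id, matrices=matrices)


def true_energy(truth: dict[str, np.ndarray], peptide: str) -> float:
    """Generative energy: offset-0 additive score, minimized over classes."""
    best = np.inf
    mapping = map_sequence(peptide, 0)
    for m in truth.values():
        e = 0.0
        for i, residue in enumerate(mapping.residues):
            if residue is not None:
                e += float(m[AA_INDEX[residue], i])
        best = min(best, e)
    return best


def simulate_spot(
    truth: dict[str, np.ndarray],
    peptides: Optional[Sequence[str]],
    noise: SpotNoiseSpec,
) -> SpotTable:
    """SPOT table with BLU = exp(-E_true) x LogNormal(0, lognormal_sd^2).

    When ``peptides`` is None, a set is generated per ``noise.composition``.
    The returned table uses pseudocount 0, so with lognormal_sd = 0 the
    derived pseudo-energy equals the generative energy exactly.
    """
    if peptides is None:
        kwargs = {} if noise.composition == "uniform" else {"anchor": noise.anchor}
        peptides = generate_sequences(
            SequenceSetSpec(
                mode=noise.composition,
                n=noise.n_peptides,
                length=noise.length,
                seed=noise.seed,
                **kwargs,
            )
        )
    rng = np.random.default_rng([noise.seed, 2])
    energies = np.array([true_energy(truth, p) for p in peptides])
    noise_factor = (
        np.exp(rng.normal(0.0, noise.lognormal_sd, size=len(energies)))
        if noise.lognormal_sd > 0
        else np.ones(len(energies))
    )
    blu = np.exp(-energies) * noise_factor
    return SpotTable.from_pairs(list(peptides), blu, pseudocount=0.0)


def sampling_schedule(
    t_start_ns: float, t_end_ns: float, interval_ps: float
) -> np.ndarray:
    """Inclusive uniform time grid labeling the ensemble's conformations.

    Times are returned in ns; the count is floor((t_end - t_start)/interval) + 1.
    The production-shaped schedule, 2-5 ns at 300 ps, gives 11 points.
    """
    if interval_ps <= 0:
        raise ValueError("interval must be positive")
    if t_end_ns <= t_start_ns:
        raise ValueError("t_end must be after t_start")
    span_ps = (t_end_ns - t_start_ns) * 1000.0
    n = int(np.floor(span_ps / interval_ps + 1e-9)) + 1
    return t_start_ns + np.arange(n) * interval_ps / 1000.0


def write_fixture(
    directory: str | Path,
    truth_spec: TruthSpec,
    spot_spec: Optional[SpotNoiseSpec] = None,
    peptides: Optional[Sequence[str]] = None,
) -> Path:
    """Write a complete fixture: matrices, manifest, truth metadata, SPOT table."""
    directory = Path(directory)
    truth, meta = simulate_truth(truth_spec)
    ensemble = simulate_ensemble(truth, truth_spec)
    write_ensemble(ensemble, directory)
    meta["n_templates"] = truth_spec.n_templates
    meta["n_conformations"] = truth_spec.n_conformations
    meta["class_split"] = list(truth_spec.class_split)
    meta["template_sd"] = truth_spec.template_sd
    meta["conformation_sd"] = truth_spec.conformation_sd
    if spot_spec is not None:
        spot = simulate_spot(truth, peptides, spot_spec)
        write_spot_table(spot, directory / "spot.tsv")
        meta["spot"] = {
            "seed": spot_spec.seed,
            "n_peptides": len(spot),
            "lognormal_sd": spot_spec.lognormal_sd,
            "composition": spot_spec.composition,
        }
    (directory / "truth.json").write_text(json.dumps(meta, indent=2) + "\n")
    return directory
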