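"""Ensemble binding-energy prediction.

A binding state is represented by multiple conformations of one peptide
template; its energy is the mean of the *n* lowest per-conformation
additive energies.  Each peptide is scored against every candidate template
over a range of sequence-to-structure registers (offsets); the register is
shared across the conformations of a template (one register per binding
mode) and the (template, offset) pair with the lowest combined energy is
reported as the predicted binding mode.

Template candidates can be all templates (minimum-energy selection), the
templates whose class matches the peptide's canonical motif, or a fixed
template id.  All ties break deterministically (offset closest to 0 then
more negative; lowest template id) so repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .matrixio import AA_INDEX, N_POSITIONS, MatrixEnsemble
from .scoring import (
    MotifClass,
    best_offset,
    detect_motif_class,
    map_sequence,
    offset_preference_order,
    score_mapping,
)

#: batch rows processed per scoring block (bounds the (n, O, T, C) buffer)
_CHUNK = 4096


class ConfigurationError(ValueError):
    """Raised when a prediction configuration is inconsistent with the ensemble."""


@dataclass(frozen=True)
class PredictionConfig:
    """Knobs of the prediction pipeline.

    n_lowest
        How many of the lowest per-conformation energies are averaged into
        the binding energy (default: all conformations).
    offset_min, offset_max
        Inclusive register range searched (default -4..4).
    template_selection
        ``min_energy`` (argmin over all templates), ``motif_class`` (restrict
        to templates matching the peptide's canonical motif class, falling
        back to all templates for motif-free or dual-motif peptides), or
        ``fixed:<id>``.
    conformation_mode
        ``ensemble`` (n-lowest averaging over all conformations) or
        ``single:<id>`` (one fixed conformation).
    per_conformation_offset
        Sensitivity option: let every conformation pick its own register
        before averaging, instead of one shared register per template.
    normalize_coverage
        Optional per-position mean normalization (energy / n_assigned) to
        offset the coverage bias of partial registers; off by default.
    """

    n_lowest: Optional[int] = None
    offset_min: int = -4
    offset_max: int = 4
    template_selection: str = "min_energy"
    conformation_mode: str = "ensemble"
    per_conformation_offset: bool = False
    normalize_coverage: bool = False

    def __post_init__(self) -> None:
        if self.offset_min > self.offset_max:
            raise ConfigurationError("offset_min must be <= offset_max")
        if self.n_lowest is not None and self.n_lowest < 1:
            raise ConfigurationError("n_lowest must be >= 1")
        sel = self.template_selection
        if sel not in ("min_energy", "motif_class") and not sel.startswith("fixed:"):
            raise ConfigurationError(f"unknown template_selection {sel!r}")
        if sel.startswith("fixed:"):
            self.fixed_template_id  # validates
        mode = self.conformation_mode
        if mode != "ensemble" and not mode.startswith("single:"):
            raise ConfigurationError(f"unknown conformation_mode {mode!r}")
        if mode.startswith("single:"):
            self.single_conformation_id  # validates

    @property
    def offsets(self) -> range:
        return range(self.offset_min, self.offset_max + 1)

    @property
    def fixed_template_id(self) -> Optional[int]:
        if self.template_selection.startswith("fixed:"):
            try:
                return int(self.template_selection.split(":", 1)[1])
            except ValueError:
                raise ConfigurationError(
                    f"bad fixed template id in {self.template_selection!r}"
                ) from None
        return None

    @property
    def single_conformation_id(self) -> Optional[int]:
        if self.conformation_mode.startswith("single:"):
            try:
                return int(self.conformation_mode.split(":", 1)[1])
            except ValueError:
                raise ConfigurationError(
                    f"bad conformation id in {self.conformation_mode!r}"
                ) from None
        return None


@dataclass
class BindingPrediction:
    """Predicted binding mode and energy of one peptide."""

    peptide: str
    energy: float
    template_id: int
    template_class: str
    offset: int
    per_conformation_energies: tuple[tuple[int, float], ...]
    n_assigned: int
    motif_class: MotifClass


def n_lowest_average(energies: Sequence[float], n: int) -> float:
    """Mean of the ``n`` smallest values; n=1 is the minimum, n=len the mean."""
    arr = np.sort(np.asarray(energies, dtype=np.float64))
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("energies must be a non-empty 1-D sequence")
    if not 1 <= n <= arr.size:
        raise ValueError(f"n must be in 1..{arr.size}, got {n}")
    return float(arr[:n].mean())


def _encode_batch(sequences: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    if not sequences:
        return np.zeros((0, 1), dtype=np.intp), np.zeros(0, dtype=np.intp)
    lengths = np.empty(len(sequences), dtype=np.intp)
    for k, s in enumerate(sequences):
        if not s:
            raise ValueError(f"sequence at index {k} is empty")
        lengths[k] = len(s)
    codes = np.zeros((len(sequences), int(lengths.max())), dtype=np.intp)
    for k, s in enumerate(sequences):
        try:
            codes[k, : len(s)] = [AA_INDEX[a] for a in s]
        except KeyError as exc:
            raise ValueError(
                f"sequence at index {k} ({s!r}) contains non-canonical "
                f"residue {exc.args[0]!r}"
            ) from None
    return codes, lengths


def _raw_energies(
    E: np.ndarray,
    codes: np.ndarray,
    lengths: np.ndarray,
    offsets: Sequence[int],
) -> np.ndarray:
    """Per-(sequence, offset, template, conformation) additive energies.

    Accumulates position by position in ascending order, exactly mirroring
    :func:`sh3score.scoring.score_mapping`; uncovered positions add 0.
    """
    T, C, _, P = E.shape
    n, Lmax = codes.shape
    # residue-major layout so one fancy-index yields (n, T, C)
    Etc = np.ascontiguousarray(E.transpose(2, 3, 0, 1))
    acc = np.zeros((n, len(offsets), T, C))
    for oi, o in enumerate(offsets):
        for i in range(1, P + 1):
            j = i - o
            if j < 1 or j > Lmax:
                continue
            vals = Etc[codes[:, j - 1], i - 1]
            uncovered = lengths < j
            if uncovered.any():
                vals[uncovered] = 0.0
            acc[:, oi] += vals
    return acc


def _n_assigned_table(
    lengths: np.ndarray, offsets: Sequence[int], n_positions: int = N_POSITIONS
) -> np.ndarray:
    """Coverage count per (sequence, offset)."""
    i = np.arange(1, n_positions + 1)
    out = np.empty((len(lengths), len(offsets)), dtype=np.intp)
    for oi, o in enumerate(offsets):
        j = i - o
        valid = j >= 1
        out[:, oi] = (valid[None, :] & (j[None, :] <= lengths[:, None])).sum(axis=1)
    return out


def _combined_energies(
    acc: np.ndarray, n_eff: int
) -> np.ndarray:
    """n-lowest average over the conformation axis -> (n, O, T)."""
    s = np.sort(acc, axis=3)
    return s[..., :n_eff].mean(axis=3)


def _resolve_conformations(
    ensemble: MatrixEnsemble, config: PredictionConfig
) -> tuple[list[int], int]:
    c_ids = ensemble.conformation_ids
    single = config.single_conformation_id
    if single is not None:
        if single not in c_ids:
            raise ConfigurationError(
                f"conformation {single} not in ensemble (has {c_ids})"
            )
        return [single], 1
    n_eff = config.n_lowest if config.n_lowest is not None else len(c_ids)
    if n_eff > len(c_ids):
        raise ConfigurationError(
            f"n_lowest={n_eff} exceeds the {len(c_ids)} available conformations"
        )
    return c_ids, n_eff


def _candidate_mask(
    ensemble: MatrixEnsemble,
    motif_classes: Sequence[MotifClass],
    config: PredictionConfig,
) -> np.ndarray:
    """(n, T) boolean mask of allowed templates per sequence."""
    t_ids = ensemble.template_ids
    n = len(motif_classes)
    mask = np.ones((n, len(t_ids)), dtype=bool)
    fixed = config.fixed_template_id
    if fixed is not None:
        if fixed not in t_ids:
            raise ConfigurationError(f"fixed template {fixed} not in ensemble")
        mask[:] = False
        mask[:, t_ids.index(fixed)] = True
        return mask
    if config.template_selection == "motif_class":
        class_mask = {
            cls: np.array([ensemble.class_of[t] == cls for t in t_ids])
            for cls in ("I", "II")
        }
        for cls, cm in class_mask.items():
            if not cm.any() and any(mc.value == cls for mc in motif_classes):
                raise ConfigurationError(
                    f"motif_class selection requires class {cls} templates, "
                    "but the ensemble has none"
                )
        for k, mc in enumerate(motif_classes):
            if mc in (MotifClass.I, MotifClass.II):
                mask[k] = class_mask[mc.value]
        # motif-free / dual-motif peptides fall back to all templates
    return mask


def predict_batch(
    ensemble: MatrixEnsemble,
    sequences: Sequence[str],
    config: PredictionConfig | None = None,
) -> list[BindingPrediction]:
    """Order-preserving batch prediction (deterministic, vectorized)."""
    config = config or PredictionConfig()
    if config.per_conformation_offset:
        return [
            _predict_per_conformation_offset(ensemble, s, config) for s in sequences
        ]
    if not sequences:
        return []
    E_full, t_ids, c_ids_all = ensemble.as_array()
    c_ids, n_eff = _resolve_conformations(ensemble, config)
    c_idx = [c_ids_all.index(c) for c in c_ids]
    E = E_full[:, c_idx]
    offsets = offset_preference_order(config.offsets)
    motif_classes = [detect_motif_class(s) for s in sequences]

    results: list[BindingPrediction] = []
    for start in range(0, len(sequences), _CHUNK):
        block = list(sequences[start : start + _CHUNK])
        codes, lengths = _encode_batch(block)
        acc = _raw_energies(E, codes, lengths, offsets)  # (n, O, T, C)
        combined = _combined_energies(acc, n_eff)  # (n, O, T)
        if config.normalize_coverage:
            n_assigned = _n_assigned_table(lengths, offsets)
            denom = np.maximum(n_assigned, 1)[:, :, None]
            combined = combined / denom
        # best offset per (sequence, template): offsets are in preference
        # order, argmin keeps the first minimum -> tie-break is built in
        o_best = np.argmin(combined, axis=1)  # (n, T)
        e_best = np.take_along_axis(combined, o_best[:, None, :], axis=1)[:, 0, :]
        mask = _candidate_mask(
            ensemble, motif_classes[start : start + len(block)], config
        )
        e_masked = np.where(mask, e_best, np.inf)
        t_best = np.argmin(e_masked, axis=1)  # first minimum -> lowest id
        n_assigned_all = _n_assigned_table(lengths, offsets)
        for k, seq in enumerate(block):
            ti = int(t_best[k])
            oi = int(o_best[k, ti])
            per_conf = tuple(
                (c_ids[ci], float(acc[k, oi, ti, ci])) for ci in range(len(c_ids))
            )
            results.append(
                BindingPrediction(
                    peptide=seq,
                    energy=float(e_masked[k, ti]),
                    template_id=t_ids[ti],
                    template_class=ensemble.class_of[t_ids[ti]],
                    offset=offsets[oi],
                    per_conformation_energies=per_conf,
                    n_assigned=int(n_assigned_all[k, oi]),
                    motif_class=motif_classes[start + k],
                )
            )
    return results


def predict(
    ensemble: MatrixEnsemble,
    sequence: str,
    config: PredictionConfig | None = None,
) -> BindingPrediction:
    """Predict the binding mode and energy of one peptide."""
    return predict_batch(ensemble, [sequence], config)[0]


def template_energy(
    ensemble: MatrixEnsemble,
    template_id: int,
    sequence: str,
    config: PredictionConfig | None = None,
) -> tuple[int, float, tuple[tuple[int, float], ...]]:
    """Best register and combined energy of ``sequence`` on one template.

    Returns ``(offset, energy, per_conformation_energies)`` where the
    per-conformation energies are evaluated at the chosen shared register.
    """
    config = config or PredictionConfig()
    if template_id not in ensemble.template_ids:
        raise ConfigurationError(f"template {template_id} not in ensemble")
    fixed = replace(config, template_selection=f"fixed:{template_id}")
    pred = predict_batch(ensemble, [sequence], fixed)[0]
    return pred.offset, pred.energy, pred.per_conformation_energies


def _predict_per_conformation_offset(
    ensemble: MatrixEnsemble, sequence: str, config: PredictionConfig
) -> BindingPrediction:
    """Sensitivity mode: every conformation optimizes its own register."""
    c_ids, n_eff = _resolve_conformations(ensemble, config)
    motif = detect_motif_class(sequence)
    mask = _candidate_mask(ensemble, [motif], config)[0]
    t_ids = ensemble.template_ids
    best: Optional[tuple] = None
    for ti, t in enumerate(t_ids):
        if not mask[ti]:
            continue
        per_conf = []
        for c in c_ids:
            o, e = best_offset(
                ensemble.matrices[(t, c)], sequence, config.offsets
            )
            per_conf.append((c, e, o))
        energies = [e for _, e, _ in per_conf]
        combined = n_lowest_average(energies, n_eff)
        if config.normalize_coverage:
            raise ConfigurationError(
                "normalize_coverage is not supported with per_conformation_offset"
            )
        if best is None or combined < best[0]:
            c_min, e_min, o_min = min(per_conf, key=lambda x: (x[1], x[0]))
            best = (combined, t, o_min, tuple((c, e) for c, e, _ in per_conf))
    assert best is not None
    combined, t, offset, per_conf = best
    mapping = map_sequence(sequence, offset)
    return BindingPrediction(
        peptide=sequence,
        energy=float(combined),
        template_id=t,
        template_class=ensemble.class_of[t],
        offset=offset,
        per_conformation_energies=per_conf,
        n_assigned=mapping.n_assigned,
        motif_class=motif,
    )


def predictions_to_frame(predictions: Sequence[BindingPrediction]) -> pd.DataFrame:
    """Tabular view used by the TSV output format."""
    return pd.DataFrame(
        {
            "peptide": [p.peptide for p in predictions],
            "energy": [p.energy for p in predictions],
            "template_id": [p.template_id for p in predictions],
            "template_class": [p.template_class for p in predictions],
            "offset": [p.offset for p in predictions],
            "n_assigned": [p.n_assigned for p in predictions],
            "motif_class": [p.motif_class.value for p in predictions],
        }
    )


def write_predictions(
    predictions: Sequence[BindingPrediction], path: str | Path
) -> None:
    predictions_to_frame(predictions).to_csv(path, sep="\t", index=False)
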