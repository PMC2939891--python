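"""Evaluation of predicted binding energies against SPOT-style affinity data.

Predicted energies are compared with the pseudo-energies derived from BLU
intensities by Pearson correlation.  The conformation study contrasts three
strategies — a single arbitrary MD snapshot (mean +/- sd over snapshots),
the single snapshot that correlates best with the data (label-peeking, so
reported only as an evaluation-time reference), and the full structural
ensemble.  Binder/non-binder discrimination is measured by the area under
the ROC curve on the k strongest vs k weakest spots.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import PredictionConfig, predict_batch
from .matrixio import MatrixEnsemble, SpotTable


class EvaluationError(ValueError):
    """Raised when a statistic is undefined for the given inputs."""


def pearson(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Product-moment correlation, with the degenerate cases rejected."""
    x = np.asarray(pred, dtype=np.float64)
    y = np.asarray(obs, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise EvaluationError("pred and obs must be equal-length 1-D sequences")
    if x.size < 3:
        raise EvaluationError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EvaluationError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class EvaluationReport:
    """Correlation summary mirroring the single / best / ensemble comparison."""

    pearson_r: float
    n: int
    per_conformation_r: Optional[list[tuple[int, float]]] = None
    best_conformation_id: Optional[int] = None
    best_single_r: Optional[float] = None
    mean_single_r: Optional[float] = None
    sd_single_r: Optional[float] = None
    aroc: Optional[float] = None

    def summary(self) -> str:
        lines = ["conformation study (Pearson r vs SPOT pseudo-energy)"]
        if self.mean_single_r is not None:
            lines.append(
                f"  single conformation : {self.mean_single_r:.3f}"
                f" +/- {self.sd_single_r:.3f}"
            )
        if self.best_single_r is not None:
            lines.append(
                f"  best conformation   : {self.best_single_r:.3f}"
                f" (conformation {self.best_conformation_id})"
            )
        lines.append(f"  ensemble            : {self.pearson_r:.3f}")
        lines.append(f"  n peptides          : {self.n}")
        if self.aroc is not None:
            lines.append(f"  AROC                : {self.aroc:.3f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "mean_single_r": self.mean_single_r,
            "sd_single_r": self.sd_single_r,
            "best_single_r": self.best_single_r,
            "best_conformation_id": self.best_conformation_id,
            "ensemble_r": self.pearson_r,
            "n": self.n,
            "aroc": self.aroc,
        }
        return pd.DataFrame([rows])


def conformation_study(
    ensemble: MatrixEnsemble,
    spot: SpotTable,
    config: PredictionConfig | None = None,
) -> EvaluationReport:
    """Compare single-conformation, best-conformation and ensemble prediction.

    For each conformation the peptides are scored with that conformation
    alone (register and template still optimized) and correlated with the
    SPOT pseudo-energies; the ensemble column uses ``config`` as given.
    Note the "best conformation" peeks at the observed data by construction.
    """
    config = config or PredictionConfig()
    if ensemble.n_conformations < 2:
        raise EvaluationError("conformation study needs >= 2 conformations")
    obs = spot.energy
    peptides = spot.peptides
    per_conf: list[tuple[int, float]] = []
    for c in ensemble.conformation_ids:
        cfg = replace(config, conformation_mode=f"single:{c}", n_lowest=None)
        preds = predict_batch(ensemble, peptides, cfg)
        per_conf.append((c, pearson([p.energy for p in preds], obs)))
    rs = np.array([r for _, r in per_conf])
    best_idx = int(np.argmax(rs))
    ens_cfg = replace(config, conformation_mode="ensemble")
    ens_preds = predict_batch(ensemble, peptides, ens_cfg)
    ens_r = pearson([p.energy for p in ens_preds], obs)
    return EvaluationReport(
        pearson_r=ens_r,
        n=len(peptides),
        per_conformation_r=per_conf,
        best_conformation_id=per_conf[best_idx][0],
        best_single_r=float(rs[best_idx]),
        mean_single_r=float(rs.mean()),
        sd_single_r=float(rs.std(ddof=1)),
    )


def spot_binder_labels(spot: SpotTable, k: int) -> pd.Series:
    """Label the k strongest spots binders (1) and the k weakest non-binders (0).

    Strength is BLU descending; the middle rows are discarded.  Ties at the
    boundaries are broken by input order.  Returns a Series indexed by row
    position over the 2k labeled rows.
    """
    n = len(spot)
    if k < 1:
        raise EvaluationError("k must be >= 1")
    if 2 * k > n:
        raise EvaluationError(f"2k = {2 * k} exceeds table size {n}")
    order = np.argsort(-spot.blu, kind="stable")
    binders = order[:k]
    non_binders = order[n - k :]
    idx = np.concatenate([binders, non_binders])
    values = np.concatenate([np.ones(k, dtype=int), np.zeros(k, dtype=int)])
    series = pd.Series(values, index=idx, name="binder")
    return series.sort_index()


def aroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve, tie-corrected.

    Lower score means stronger predicted binding, so perfect separation of
    binders (label 1) below non-binders gives 1.0.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise EvaluationError("scores and labels must be equal-length 1-D")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise EvaluationError("both classes must be non-empty")
    ranks = stats.rankdata(s)
    r1 = ranks[y == 1].sum()
    # U counts (non-binder below binder) pairs + half ties
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return float(1.0 - u1 / (n1 * n0))
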