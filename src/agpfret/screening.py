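"""Pose screening against measured FRET efficiencies.

For each candidate pose the expected efficiency at every Agp1 acceptor
position is predicted from the donor-acceptor distance matrix (Förster law,
occupancy-weighted monomer aggregation, two-channel combination), scored
against the measured table by a sum of squared differences, and filtered by
three selection criteria that deliberately avoid absolute-scale comparisons
(the absolute measured efficiencies depend on unknown labeling yields):

* C1 — the position-554 efficiency exceeds the position-122 efficiency
  (largest, significant contrast in the measurements);
* C2 — the position-362 efficiency is substantially below position 554
  (measured 0.10 vs 0.28, a significant difference); operationalized as
  E554 - E362 exceeding a margin on the measurement-uncertainty scale
  (default 0.05, the order of the reported standard errors);
* C3 — the domain-involvement pattern matches the truncation experiments:
  Agp1 interacts through its histidine kinase, not its PCM, while Agp2
  interacts through its PCM, not its kinase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import fret_core
from .exceptions import InvalidArgumentError
from .fret_core import FretParams
from .structure_io import DistanceMatrix, LabelingScheme, StructureModel, distance_matrix

#: Default criterion-2 margin: E(554) must exceed E(362) by this much
#: (the scale of the reported measurement standard errors, 0.02-0.06).
DEFAULT_C2_MARGIN = 0.05


@dataclass(frozen=True)
class EfficiencySet:
    """Measured or predicted efficiency per Agp1 label position."""

    efficiencies: Mapping[int, float]
    standard_errors: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        eff = dict(self.efficiencies)
        object.__setattr__(self, "efficiencies", eff)
        object.__setattr__(self, "standard_errors", dict(self.standard_errors))
        for pos, e in eff.items():
            if not 0.0 <= e <= 1.0:
                raise InvalidArgumentError(f"efficiency at position {pos} outside [0, 1]: {e}")

    def positions(self) -> tuple:
        return tuple(sorted(self.efficiencies))

    def __getitem__(self, position: int) -> float:
        return self.efficiencies[position]

    def as_series(self) -> pd.Series:
        return pd.Series(self.efficiencies).sort_index()


@dataclass(frozen=True)
class InvolvementFlags:
    """Which module of each protein carries interface contacts."""

    agp1_pcm: bool = False
    agp1_hk: bool = False
    agp2_pcm: bool = False
    agp2_hk: bool = False


@dataclass(frozen=True)
class DomainRanges:
    """PCM / histidine-kinase residue intervals per protein (construct numbering).

    Boundaries are configuration: the Agp1 PCM construct ends near the
    PHY-kinase linker (residue ~517, the most C-terminal PCM label), the
    kinase follows; similarly for Agp2, whose C-terminal module also includes
    the response regulator.
    """

    agp1_pcm: tuple = (1, 517)
    agp1_hk: tuple = (518, 1000)
    agp2_pcm: tuple = (1, 501)
    agp2_hk: tuple = (502, 1000)

    def __post_init__(self) -> None:
        for a, b in (
            (self.agp1_pcm, self.agp1_hk),
            (self.agp2_pcm, self.agp2_hk),
        ):
            if a[1] >= b[0]:
                raise InvalidArgumentError(f"domain intervals overlap: {a} vs {b}")


@dataclass(frozen=True)
class ModelScore:
    """Screening result for one pose."""

    model_id: str
    predicted: EfficiencySet
    ssd: float
    involvement: InvolvementFlags = InvolvementFlags()
    criteria: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ssd < 0:
            raise InvalidArgumentError("ssd must be >= 0")


def predict_position_efficiency(
    model: StructureModel,
    scheme: LabelingScheme,
    params: FretParams = FretParams(),
    numbering_offsets: Mapping[str, int] | None = None,
    combination_mode: str = "mean_then_combine",
) -> EfficiencySet:
    """Predicted efficiency for every configured Agp1 acceptor position.

    For each position, the pair efficiencies of its two acceptor sites
    against all donor sites are aggregated per monomer (occupancy-weighted
    mean) and combined across monomers.  ``combination_mode`` selects the
    published order of operations (``mean_then_combine``, default) or the
    per-configuration alternative (``combine_then_mean``).
    """
    if combination_mode not in ("mean_then_combine", "combine_then_mean"):
        raise InvalidArgumentError(f"unknown combination_mode {combination_mode!r}")
    dm = distance_matrix(model, scheme, numbering_offsets)
    pair_e = fret_core.forward_efficiency(dm.distances, params)
    weights = scheme.donor_weights
    w = weights / weights.sum() if abs(weights.sum() - 1.0) > 1e-9 else weights

    out = {}
    for pos in scheme.acceptor_positions():
        row_idx = [
            i for i, s in enumerate(scheme.acceptor_sites) if s.residue_number == pos
        ]
        per_monomer = [
            fret_core.aggregate_monomer_efficiency(pair_e[i], w) for i in row_idx
        ]
        if combination_mode == "combine_then_mean" and len(row_idx) == 2:
            out[pos] = fret_core.combine_alternative(pair_e[row_idx[0]], pair_e[row_idx[1]], w)
        elif len(per_monomer) == 1:
            out[pos] = per_monomer[0]
        else:
            total = per_monomer[0]
            for e in per_monomer[1:]:
                total = fret_core.combine_total(total, e)
            out[pos] = total
    return EfficiencySet(out)


def score_model(
    predicted: EfficiencySet,
    measured: EfficiencySet,
    space: str = "efficiency",
) -> float:
    """Sum of squared differences between predicted and measured values.

    ``space='efficiency'`` compares efficiencies directly;
    ``space='distance'`` compares relative distances ``(1/E - 1)^(1/6)``
    (positions where either value is outside (0, 1) cannot be inverted and
    are rejected there).
    """
    if space not in ("efficiency", "distance"):
        raise InvalidArgumentError(f"unknown scoring space {space!r}")
    p_keys, m_keys = set(predicted.positions()), set(measured.positions())
    if p_keys != m_keys:
        raise InvalidArgumentError(
            f"position keys differ: only-predicted {sorted(p_keys - m_keys)}, "
            f"only-measured {sorted(m_keys - p_keys)}"
        )
    total = 0.0
    for pos in sorted(p_keys):
        a, b = predicted[pos], measured[pos]
        if space == "distance":
            a, b = fret_core.relative_distance(a), fret_core.relative_distance(b)
        total += (a - b) ** 2
    return total


def classify_domain_involvement(contacts, ranges: DomainRanges = DomainRanges()) -> InvolvementFlags:
    """Flag each protein module that carries at least one interface contact.

    ``contacts`` is an iterable of ContactPair (see interface_contacts).
    Residues outside every configured interval count toward neither module.
    """
    flags = {"agp1_pcm": False, "agp1_hk": False, "agp2_pcm": False, "agp2_hk": False}
    intervals = {
        "agp1_pcm": ranges.agp1_pcm,
        "agp1_hk": ranges.agp1_hk,
        "agp2_pcm": ranges.agp2_pcm,
        "agp2_hk": ranges.agp2_hk,
    }
    for pair in contacts:
        for protein, resnum in (
            ("agp1", pair.agp1_residue[1]),
            ("agp2", pair.agp2_residue[1]),
        ):
            hit = False
            for module in ("pcm", "hk"):
                lo, hi = intervals[f"{protein}_{module}"]
                if lo <= resnum <= hi:
                    flags[f"{protein}_{module}"] = True
                    hit = True
            if not hit:
                import logging

                logging.getLogger(__name__).warning(
                    "contact residue %s %d outside all domain intervals", protein, resnum
                )
    return InvolvementFlags(**flags)


def evaluate_criteria(
    predicted: EfficiencySet,
    involvement: InvolvementFlags,
    c1_margin: float = 0.0,
    c2_margin: float = DEFAULT_C2_MARGIN,
) -> dict:
    """Per-criterion verdicts for one pose.

    C1: ``E(554) - E(122) > c1_margin`` (strict if margin 0).
    C2: ``E(554) - E(362) > c2_margin``.
    C3: involvement pattern equals (agp1_hk, not agp1_pcm, agp2_pcm,
    not agp2_hk).
    """
    for pos in (122, 362, 554):
        if pos not in predicted.efficiencies:
            raise InvalidArgumentError(f"criteria need position {pos}, missing from prediction")
    e122, e362, e554 = predicted[122], predicted[362], predicted[554]
    return {
        "c1_122_vs_554": e554 - e122 > c1_margin,
        "c2_362_vs_554": e554 - e362 > c2_margin,
        "c3_domain_involvement": (
            involvement.agp1_hk
            and not involvement.agp1_pcm
            and involvement.agp2_pcm
            and not involvement.agp2_hk
        ),
    }


def apply_selection_criteria(
    scores: Sequence[ModelScore],
    c1_margin: float = 0.0,
    c2_margin: float = DEFAULT_C2_MARGIN,
):
    """Filter poses by C1 ∧ C2 ∧ C3 with a per-model audit trail.

    Returns ``(survivors, audit)`` where ``audit`` is a DataFrame with one
    row per input model, its three verdicts and, for eliminated models, the
    first criterion that removed it.
    """
    survivors, rows = [], []
    for score in scores:
        verdicts = evaluate_criteria(score.predicted, score.involvement, c1_margin, c2_margin)
        eliminated_by = next((k for k, ok in verdicts.items() if not ok), None)
        keep = eliminated_by is None
        if keep:
            survivors.append(replace(score, criteria=verdicts))
        rows.append({"model_id": score.model_id, **verdicts,
                     "selected": keep, "eliminated_by": eliminated_by or ""})
    return survivors, pd.DataFrame(rows)


def sample_weights(rng: np.random.Generator, n_sites: int, max_fold: float) -> np.ndarray:
    """One normalized occupancy-weight vector with max/min <= max_fold.

    Per-site weights are log-uniform on [1, max_fold] before normalization,
    so the fold bound holds by construction; a rejection guard remains as a
    safety net.
    """
    if max_fold < 1:
        raise InvalidArgumentError(f"max_fold must be >= 1, got {max_fold}")
    for _ in range(1000):
        w = np.exp(rng.uniform(0.0, np.log(max_fold) if max_fold > 1 else 0.0, n_sites))
        if w.max() / w.min() <= max_fold + 1e-9:
            return w / w.sum()
    raise InvalidArgumentError("could not draw a weight vector within the fold bound")


def robustness_resample(
    model: StructureModel,
    scheme: LabelingScheme,
    params: FretParams = FretParams(),
    n_samples: int = 1000,
    max_fold: float = 40.0,
    seed: int = 0,
    numbering_offsets: Mapping[str, int] | None = None,
):
    """Stability of predicted-efficiency orderings under unequal occupancies.

    Draws ``n_samples`` donor occupancy-weight vectors spanning at most a
    ``max_fold`` ratio between sites, recomputes every position efficiency
    per sample, and reports for each position pair the fraction of samples
    preserving the ordering obtained under uniform weights.

    Returns ``(samples, stability)``: a DataFrame of per-sample efficiencies
    (one row per sample, one column per position) and a DataFrame with
    columns ``pos_hi, pos_lo, fraction_preserved`` for each position pair
    ordered by the uniform-weight prediction.
    """
    if n_samples < 1:
        raise InvalidArgumentError("n_samples must be >= 1")
    if max_fold < 1:
        raise InvalidArgumentError(f"max_fold must be >= 1, got {max_fold}")
    rng = np.random.default_rng(seed)
    n_donors = len(scheme.donor_sites)

    # pair efficiencies depend only on geometry; reweighting reuses them
    dm = distance_matrix(model, scheme, numbering_offsets)
    pair_e = fret_core.forward_efficiency(dm.distances, params)
    positions = scheme.acceptor_positions()
    rows_by_pos = {
        pos: [i for i, s in enumerate(scheme.acceptor_sites) if s.residue_number == pos]
        for pos in positions
    }

    def predict_with(w):
        out = {}
        for pos, rows in rows_by_pos.items():
            total = float(pair_e[rows[0]] @ w)
            for i in rows[1:]:
                total = fret_core.combine_total(total, float(pair_e[i] @ w))
            out[pos] = total
        return out

    uniform = predict_with(np.full(n_donors, 1.0 / n_donors))
    records = [predict_with(sample_weights(rng, n_donors, max_fold)) for _ in range(n_samples)]
    samples = pd.DataFrame(records)

    rows = []
    for i, a in enumerate(positions):
        for b in positions[i + 1:]:
            hi, lo = (a, b) if uniform[a] >= uniform[b] else (b, a)
            frac = float(np.mean(samples[hi].to_numpy() >= samples[lo].to_numpy()))
            rows.append({"pos_hi": hi, "pos_lo": lo, "fraction_preserved": frac})
    stability = pd.DataFrame(rows)
    return samples, stability


def screen_models(
    models: Iterable[StructureModel],
    scheme: LabelingScheme,
    measured: EfficiencySet,
    params: FretParams = FretParams(),
    ssd_space: str = "efficiency",
    numbering_offsets: Mapping[str, int] | None = None,
    contact_fn=None,
) -> list:
    """Predict, score and flag every pose; returns a list of ModelScore.

    ``contact_fn(model) -> InvolvementFlags`` supplies domain involvement
    when contact analysis is wanted; by default flags stay all-False.
    """
    out = []
    for model in models:
        predicted = predict_position_efficiency(model, scheme, params, numbering_offsets)
        ssd = score_model(predicted, measured, ssd_space)
        involvement = contact_fn(model) if contact_fn is not None else InvolvementFlags()
        out.append(ModelScore(model.model_id, predicted, ssd, involvement))
    return out


def scores_to_frame(scores: Sequence[ModelScore]) -> pd.DataFrame:
    """Tabulate ModelScores: one row per pose, one column per position + ssd."""
    rows = []
    for s in scores:
        row = {"model_id": s.model_id}
        row.update({f"E{pos}": s.predicted[pos] for pos in s.predicted.positions()})
        row["ssd"] = s.ssd
        row.update(
            {
                "agp1_pcm": s.involvement.agp1_pcm,
                "agp1_hk": s.involvement.agp1_hk,
                "agp2_pcm": s.involvement.agp2_pcm,
                "agp2_hk": s.involvement.agp2_hk,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
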