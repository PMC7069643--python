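"""Nutrient-imbalance diagnosis against banks of balanced references.

High-yielding specimens that the best classifier also *predicts* as
high-yielding (true negatives, in the medical polarity where positive means
intervention needed) form per-cultivar reference banks: pockets of
nutritionally balanced compositions scattered through clr space. A new or
imbalanced specimen is diagnosed by finding the bank composition at minimum
Aitchison distance (over the five measured nutrients) and expressing the
correction as a perturbation vector — the multiplicative translation that
carries the observed composition exactly onto its nearest balanced
reference. The sign of each nutrient's clr difference (reference −
observed) labels it apparently deficient or in excess, and the magnitudes
rank the corrections.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coda import (NUTRIENTS, PARTS, ClrVector, Composition, ImbalanceEntry,
                   PerturbationVector, clr_inverse, clr_transform, close,
                   perturbation_difference, rank_imbalance, subcomposition)
from .classify import NEGATIVE_CLASS, TrainedModel, predict

__all__ = ["ReferenceBank", "DiagnosisResult", "build_reference_bank",
           "nearest_reference", "diagnose", "simulate_clr_perturbation"]

SAME_CULTIVAR = "same-cultivar"
CROSS_CULTIVAR = "cross-cultivar"


def _nutrient_clr(values: np.ndarray) -> np.ndarray:
    """clr of the 5-nutrient subcomposition of 6-part rows (vectorised)."""
    sub = np.asarray(values, dtype=float)[..., :len(NUTRIENTS)]
    logs = np.log(sub)
    return logs - logs.mean(axis=-1, keepdims=True)


@dataclass
class ReferenceBank:
    """Balanced reference compositions, indexed by cultivar.

    ``refs`` holds one row per reference with columns ``ref_id``,
    ``cultivar`` and the six composition parts; rows are kept sorted by
    ``ref_id`` so nearest-reference ties resolve deterministically. The clr
    of each reference's nutrient subcomposition is cached for fast search.
    """

    refs: pd.DataFrame
    model_id: str = ""
    seed: int | None = None
    _clr5: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        required = ["ref_id", "cultivar", *PARTS]
        missing = [c for c in required if c not in self.refs.columns]
        if missing:
            raise ValueError(f"reference table missing columns: {missing}")
        self.refs = (self.refs.loc[:, required]
                     .sort_values("ref_id", kind="stable")
                     .reset_index(drop=True))
        comp = self.refs.loc[:, list(PARTS)].to_numpy(dtype=float)
        if len(comp) and (np.any(comp <= 0) or
                          np.max(np.abs(comp.sum(axis=1) - 1)) > 1e-6):
            raise ValueError("reference compositions must be positive unit-sum")
        self._clr5 = _nutrient_clr(comp) if len(comp) else np.empty((0, 5))

    def __len__(self) -> int:
        return len(self.refs)

    @property
    def cultivars(self) -> tuple[str, ...]:
        return tuple(sorted(self.refs["cultivar"].unique()))

    def composition(self, ref_id) -> Composition:
        row = self.refs.loc[self.refs["ref_id"] == ref_id]
        if row.empty:
            raise KeyError(f"no reference with id {ref_id!r}")
        return Composition(row.iloc[0].loc[list(PARTS)].to_numpy(dtype=float))

    def mean_clr_norms(self) -> pd.DataFrame:
        """Per-cultivar mean clr values of the full 6-part references.

        These are the bank's nutritional norms: the centre of each
        cultivar's island of balanced compositions in clr space.
        """
        comp = self.refs.loc[:, list(PARTS)].to_numpy(dtype=float)
        logs = np.log(comp)
        clr6 = logs - logs.mean(axis=1, keepdims=True)
        tbl = pd.DataFrame(clr6, columns=[f"clr_{p}" for p in PARTS])
        tbl["cultivar"] = self.refs["cultivar"].to_numpy()
        out = tbl.groupby("cultivar").mean().reset_index()
        out.insert(1, "n", self.refs.groupby("cultivar").size()
                   .reindex(out["cultivar"]).to_numpy())
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model_id": self.model_id,
            "seed": self.seed,
            "parts": list(PARTS),
            "references": self.refs.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceBank":
        payload = json.loads(Path(path).read_text())
        refs = pd.DataFrame(payload["references"])
        return cls(refs=refs, model_id=payload.get("model_id", ""),
                   seed=payload.get("seed"))


@dataclass(frozen=True)
class DiagnosisResult:
    """Diagnosis of one specimen against a reference bank.

    ``perturbation`` is the 6-part composition that, applied with ⊕ to the
    observed composition, reproduces the nearest balanced reference.
    ``ranking`` orders the nutrients by |clr(reference) − clr(observed)|
    over the 5-nutrient subcomposition, labelling each apparently
    deficient (positive delta) or in excess (negative delta).
    """

    query_id: object
    cultivar: str | None
    reference_id: object
    reference_cultivar: str
    distance: float
    perturbation: PerturbationVector
    ranking: list[ImbalanceEntry]
    scope: str  # SAME_CULTIVAR or CROSS_CULTIVAR


def build_reference_bank(
    model: TrainedModel,
    train: pd.DataFrame,
    id_column: str | None = None,
) -> ReferenceBank:
    """Collect the training set's true negatives into a reference bank.

    A record enters the bank iff its observed yield class is high *and* the
    model predicts it high. Cultivars without a single true negative are
    simply absent from the bank (a warning lists them): specimens of those
    cultivars will be diagnosed against the nearest documented cultivar.
    """
    yhat = predict(model, train)
    y = train["yield_class"].to_numpy(dtype=str)
    tn_mask = (y == NEGATIVE_CLASS) & (yhat == NEGATIVE_CLASS)
    tn = train.loc[tn_mask]

    refs = tn.loc[:, ["cultivar", *PARTS]].copy()
    refs.insert(0, "ref_id",
                tn[id_column].to_numpy() if id_column else tn.index.to_numpy())
    # re-close: stored parts can carry rounding from file round-trips
    comp = refs.loc[:, list(PARTS)].to_numpy(dtype=float)
    refs.loc[:, list(PARTS)] = comp / comp.sum(axis=1, keepdims=True)

    absent = sorted(set(train["cultivar"]) - set(refs["cultivar"]))
    if absent:
        warnings.warn(
            f"{len(absent)} cultivars have no true-negative reference: "
            + ", ".join(map(str, absent[:5])))
    if refs.empty:
        warnings.warn("empty reference bank: the model predicted no specimen "
                      "as a balanced high-yielder")
    return ReferenceBank(refs=refs, model_id=model.algorithm, seed=model.seed)


def nearest_reference(
    query: Composition,
    cultivar: str | None,
    bank: ReferenceBank,
    scope: str = "cultivar",
) -> tuple[object, float, str]:
    """Find the bank composition at minimum Aitchison distance to the query.

    The distance is computed on the 5-nutrient subcomposition. With
    ``scope="cultivar"`` the search is restricted to the query's cultivar
    and falls back to the whole bank — flagged cross-cultivar — when the
    cultivar is absent; ``scope="global"`` always searches the whole bank.
    Ties break toward the smallest reference id.

    Returns ``(ref_id, distance, scope_flag)``.
    """
    if len(bank) == 0:
        raise ValueError("reference bank is empty")
    if scope not in ("cultivar", "global"):
        raise ValueError("scope must be 'cultivar' or 'global'")
    if tuple(query.parts) != PARTS:
        raise ValueError(f"query must be a full {PARTS} composition")

    subset = bank.refs
    flag = CROSS_CULTIVAR
    if scope == "cultivar" and cultivar is not None:
        same = bank.refs["cultivar"] == cultivar
        if same.any():
            subset = bank.refs.loc[same]
            flag = SAME_CULTIVAR

    q5 = _nutrient_clr(query.values)
    cand = bank._clr5[subset.index.to_numpy()]
    dists = np.linalg.norm(cand - q5, axis=1)
    best = int(np.argmin(dists))  # first minimum = smallest ref_id (sorted)
    return subset.iloc[best]["ref_id"], float(dists[best]), flag


def diagnose(
    query: Composition,
    bank: ReferenceBank,
    cultivar: str | None = None,
    query_id: object = None,
    scope: str = "cultivar",
) -> DiagnosisResult:
    """Full diagnosis of one composition: reference, distance, prescription.

    The perturbation vector is computed on all six parts, so applying it to
    the observed composition reproduces the chosen reference exactly; the
    distance and the excess/deficiency ranking use the 5-nutrient
    subcomposition.
    """
    ref_id, dist, flag = nearest_reference(query, cultivar, bank, scope)
    ref = bank.composition(ref_id)
    ref_cultivar = str(
        bank.refs.loc[bank.refs["ref_id"] == ref_id, "cultivar"].iloc[0])

    pert = perturbation_difference(query, ref)
    q5 = clr_transform(subcomposition(query, NUTRIENTS))
    r5 = clr_transform(subcomposition(ref, NUTRIENTS))
    delta = ClrVector(r5.values - q5.values, q5.parts)
    return DiagnosisResult(
        query_id=query_id,
        cultivar=cultivar,
        reference_id=ref_id,
        reference_cultivar=ref_cultivar,
        distance=dist,
        perturbation=pert,
        ranking=rank_imbalance(delta, parts=q5.parts, atol=1e-9),
        scope=flag,
    )


def simulate_clr_perturbation(
    c: Composition,
    components: Sequence[str],
    factor: float = 1.2,
    mode: str = "multiplicative",
) -> tuple[Composition, dict[str, float]]:
    """Shift the clr values of selected components and observe the ripple.

    With ``mode="multiplicative"`` (default) each selected component's clr
    value is multiplied by ``factor`` — a 20 % increase of the *signed* clr
    value for factor 1.2, which lowers negative clr values. With
    ``mode="additive"`` the shift is ``factor − 1`` in log-ratio units
    added to each selected clr value. The resulting vector is re-centred to
    sum zero and closed back to the simplex.

    Because of closure, perturbing any one component moves every
    proportion: the returned offsets (new − old proportion per part) are
    nonzero for non-selected parts too.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    comp_set = set(components)
    unknown = comp_set - set(c.parts)
    if unknown:
        raise ValueError(f"unknown components: {sorted(unknown)}")
    v = clr_transform(c).values.copy()
    sel = np.array([p in comp_set for p in c.parts])
    if mode == "multiplicative":
        v[sel] *= factor
    elif mode == "additive":
        v[sel] += factor - 1.0
    else:
        raise ValueError("mode must be 'multiplicative' or 'additive'")
    v -= v.mean()
    new = clr_inverse(ClrVector(v, c.parts))
    offsets = {p: float(nv - ov)
               for p, nv, ov in zip(c.parts, new.values, c.values)}
    return new, offsets
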