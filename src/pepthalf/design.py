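"""Peptide design utilities: point-mutant analogs and protein scanning.

``generate_point_analogs`` enumerates every single-residue substitution of
a parent peptide (19·L analogs); ``protein_scan`` extracts every
overlapping window of a chosen length from a protein.  Candidates can be
scored with any trained half-life model and ranked toward longer or
shorter predicted half-life.  All coordinates in reports are 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import ALPHABET, MAX_LENGTH, MIN_LENGTH
from .encoders import (
    FeatureVector,
    _check_sequence,
    encode_dataset,
    physicochemical_properties,
)
from .regression import TrainedModel


@dataclass
class DesignCandidate:
    """A designed peptide: a mutant analog or a protein window."""

    sequence: str
    parent_id: str
    position: int  # 1-based: mutated position, or window start
    predicted_log2_half_life: float | None = None
    properties: FeatureVector = field(default=None)

    def __post_init__(self):
        self.sequence = _check_sequence(self.sequence, 1)
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive, got {self.position}")
        if self.properties is None:
            self.properties = physicochemical_properties(self.sequence)

    @property
    def predicted_half_life_seconds(self) -> float | None:
        if self.predicted_log2_half_life is None:
            return None
        return float(2.0 ** self.predicted_log2_half_life)


def generate_point_analogs(sequence: str, parent_id: str = "parent") -> list[DesignCandidate]:
    """All 19·L single-point mutants, ordered by (position, alphabet).

    No analog equals the parent; each differs at exactly one position.
    """
    sequence = _check_sequence(sequence, 1)
    analogs = []
    for pos, original in enumerate(sequence):
        for substitute in ALPHABET:
            if substitute == original:
                continue
            mutant = sequence[:pos] + substitute + sequence[pos + 1 :]
            analogs.append(
                DesignCandidate(mutant, parent_id=parent_id, position=pos + 1)
            )
    return analogs


def protein_scan(
    protein: str,
    window: int,
    model: TrainedModel | None = None,
    encoder="aac",
    parent_id: str = "protein",
) -> list[DesignCandidate]:
    """All overlapping windows of length ``window`` (stride 1), optionally
    scored by a trained model.

    Window length must lie in the model validity range [5, 50] and not
    exceed the protein length; starts are 1-based, so a protein of length
    N yields N − w + 1 windows.
    """
    protein = _check_sequence(protein, 1)
    if not (MIN_LENGTH <= window <= MAX_LENGTH):
        raise ValueError(
            f"window must lie in [{MIN_LENGTH}, {MAX_LENGTH}], got {window}"
        )
    if window > len(protein):
        raise ValueError(
            f"window {window} exceeds protein length {len(protein)}"
        )
    candidates = [
        DesignCandidate(protein[s : s + window], parent_id=parent_id, position=s + 1)
        for s in range(len(protein) - window + 1)
    ]
    if model is not None:
        score_candidates(candidates, model, encoder)
    return candidates


def score_candidates(
    candidates: list[DesignCandidate], model: TrainedModel, encoder="aac"
) -> list[DesignCandidate]:
    """Predict log2 half-life for each candidate in place (and return them)."""
    if not candidates:
        return candidates
    from .dataset_io import HalfLifeDataset, PeptideRecord

    ds = HalfLifeDataset(
        [PeptideRecord(id=str(i), sequence=c.sequence, half_life_seconds=1.0)
         for i, c in enumerate(candidates)]
    )
    X = encode_dataset(ds, encoder)
    preds = model.predict(X)
    for cand, p in zip(candidates, preds):
        cand.predicted_log2_half_life = float(p)
    return candidates


def rank_designs(
    candidates: list[DesignCandidate], objective: str = "longest", top_k: int | None = None
) -> list[DesignCandidate]:
    """Sort scored candidates by predicted half-life and keep the top k.

    ``objective="longest"`` sorts descending, ``"shortest"`` ascending;
    ties keep input order (stable sort).
    """
    if objective not in ("longest", "shortest"):
        raise ValueError(f"objective must be 'longest' or 'shortest', got {objective!r}")
    for c in candidates:
        if c.predicted_log2_half_life is None:
            raise ValueError(f"candidate {c.sequence!r} has no prediction; score first")
    reverse = objective == "longest"
    ranked = sorted(
        candidates, key=lambda c: -c.predicted_log2_half_life if reverse
        else c.predicted_log2_half_life
    )
    return ranked if top_k is None else ranked[: int(top_k)]


def candidates_to_frame(candidates: list[DesignCandidate]) -> pd.DataFrame:
    """Tabular report: sequence, origin, predictions, property panel."""
    rows = []
    for c in candidates:
        row = {
            "id": f"{c.parent_id}_{c.position}_{c.sequence}",
            "sequence": c.sequence,
            "parent_id": c.parent_id,
            "position": c.position,
            "predicted_log2_half_life": c.predicted_log2_half_life,
            "predicted_half_life_seconds": c.predicted_half_life_seconds,
        }
        row.update(c.properties.to_series().to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
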