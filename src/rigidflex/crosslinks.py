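"""Cross-linking MS tables: reading, mapping onto structures, statistics.

Cross-links are unordered residue pairs with an identification score.
Records are filtered at a score cutoff (strictly greater than), collapsed
to unique unordered pairs keeping the best score, then mapped onto a
structure as Cα–Cα distances; a link is satisfied when the distance is at
or below the linker's upper bound (25 Å for the lysine-reactive PhoX
reagent). On ensembles, the per-pair contact frequency is the (weighted)
fraction of frames within the bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import Ensemble
from .structure_io import Structure, StructureError, ca_distance

__all__ = [
    "CrossLinkRecord",
    "XLMappingResult",
    "read_crosslinks",
    "map_crosslinks",
    "contact_frequency",
    "compare_ensembles",
]

DEFAULT_COLUMNS = {
    "protein_a": "protein_a", "residue_a": "residue_a",
    "protein_b": "protein_b", "residue_b": "residue_b",
    "score": "score",
}


@dataclass(frozen=True)
class CrossLinkRecord:
    """One unordered cross-linked residue pair with its best score."""

    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    score: float
    link_class: str | None = None   # inter / intra / exon1

    def __post_init__(self) -> None:
        if self.residue_a <= 0 or self.residue_b <= 0:
            raise ValueError("residue numbers must be positive")
        if self.score < 0:
            raise ValueError("score must be non-negative")

    @property
    def pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        ends = sorted([(self.chain_a, self.residue_a),
                       (self.chain_b, self.residue_b)])
        return ends[0], ends[1]

    def classify(self, exon1: tuple[str, int, int] | None = None) -> str:
        """inter-molecular / intra-molecular / exon-1 class per endpoint chains."""
        if exon1 is not None:
            chain, lo, hi = exon1
            for c, r in self.pair:
                if c == chain and lo <= r <= hi:
                    return "exon1"
        return "intra" if self.chain_a == self.chain_b else "inter"


@dataclass
class XLMappingResult:
    """Per-record Cα–Cα distances against one structure, plus summary."""

    records: list[CrossLinkRecord]
    distances: list[float | None]       # None = unmappable endpoint
    threshold: float

    @property
    def satisfied(self) -> list[bool | None]:
        return [None if d is None else d <= self.threshold
                for d in self.distances]

    @property
    def mappable(self) -> list[float]:
        return [d for d in self.distances if d is not None]

    @property
    def n_mappable(self) -> int:
        return len(self.mappable)

    @property
    def mean_distance(self) -> float:
        return float(np.mean(self.mappable)) if self.mappable else float("nan")

    @property
    def max_distance(self) -> float:
        return float(np.max(self.mappable)) if self.mappable else float("nan")

    @property
    def fraction_satisfied(self) -> float:
        d = self.mappable
        if not d:
            return float("nan")
        return float(np.mean(np.asarray(d) <= self.threshold))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec, dist, sat in zip(self.records, self.distances, self.satisfied):
            rows.append({"chain_a": rec.chain_a, "residue_a": rec.residue_a,
                         "chain_b": rec.chain_b, "residue_b": rec.residue_b,
                         "score": rec.score, "distance_A": dist,
                         "satisfied": sat})
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {"n_records": len(self.records),
                "n_mappable": self.n_mappable,
                "mean_distance_A": self.mean_distance,
                "max_distance_A": self.max_distance,
                "fraction_satisfied": self.fraction_satisfied,
                "threshold_A": self.threshold}


def read_crosslinks(path: str | Path, score_cutoff: float = 40.0,
                    columns: Mapping[str, str] | None = None,
                    exon1: tuple[str, int, int] | None = None,
                    ) -> list[CrossLinkRecord]:
    """Read a cross-link CSV, keep scores strictly above the cutoff, and
    collapse duplicate unordered pairs keeping the best score.

    ``columns`` remaps the expected column names (protein_a, residue_a,
    protein_b, residue_b, score) onto the exporter's header.
    """
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"cross-link CSV missing column(s): {missing}")
    best: dict[tuple, CrossLinkRecord] = {}
    for idx, row in df.iterrows():
        try:
            rec = CrossLinkRecord(
                chain_a=str(row[cols["protein_a"]]),
                residue_a=int(row[cols["residue_a"]]),
                chain_b=str(row[cols["protein_b"]]),
                residue_b=int(row[cols["residue_b"]]),
                score=float(row[cols["score"]]))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"bad cross-link row {idx}: {exc}") from exc
        if rec.score <= score_cutoff:
            continue
        key = rec.pair
        if key not in best or rec.score > best[key].score:
            best[key] = rec
    out = []
    for rec in best.values():
        out.append(CrossLinkRecord(
            chain_a=rec.chain_a, residue_a=rec.residue_a,
            chain_b=rec.chain_b, residue_b=rec.residue_b, score=rec.score,
            link_class=rec.classify(exon1)))
    return sorted(out, key=lambda r: r.pair)


def map_crosslinks(records: Sequence[CrossLinkRecord], structure: Structure,
                   l_0: float = 25.0) -> XLMappingResult:
    """Cα–Cα distance for each record; unresolved endpoints are unmappable
    states, not errors, and are excluded from the summary statistics."""
    if l_0 <= 0:
        raise ValueError("l_0 must be positive")
    distances: list[float | None] = []
    for rec in records:
        (ca, ra), (cb, rb) = rec.pair
        try:
            distances.append(ca_distance(structure, (ca, ra), (cb, rb)))
        except (KeyError, StructureError):
            distances.append(None)
    return XLMappingResult(records=list(records), distances=distances,
                           threshold=l_0)


def contact_frequency(ensemble: Ensemble,
                      pairs: Sequence[tuple[int, int]],
                      threshold: float = 25.0) -> np.ndarray:
    """Weighted fraction of frames in which each bead pair is within
    ``threshold`` Å; uniform weights when the ensemble carries none."""
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    w = ensemble.effective_weights()
    out = np.empty(len(pairs))
    for p, (i, j) in enumerate(pairs):
        d = np.linalg.norm(ensemble.frames[:, i] - ensemble.frames[:, j], axis=1)
        out[p] = float(np.sum(w[d <= threshold]))
    # weight sums can exceed 1 by rounding; a frequency is in [0, 1]
    return np.clip(out, 0.0, 1.0)


def compare_ensembles(freq_a: Mapping[tuple[int, int], float],
                      freq_b: Mapping[tuple[int, int], float],
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align two per-pair frequency maps.

    Returns (aligned, unshared): the aligned table has columns pair/freq_a/
    freq_b/difference sorted by |difference| descending; unshared lists
    pairs present in only one input with their source.
    """
    shared = sorted(set(freq_a) & set(freq_b))
    aligned = pd.DataFrame({
        "pair": shared,
        "freq_a": [freq_a[p] for p in shared],
        "freq_b": [freq_b[p] for p in shared],
    })
    aligned["difference"] = aligned["freq_a"] - aligned["freq_b"]
    if len(aligned):
        aligned = aligned.iloc[
            aligned["difference"].abs().sort_values(ascending=False).index
        ].reset_index(drop=True)
    rows = ([{"pair": p, "source": "a", "frequency": freq_a[p]}
             for p in sorted(set(freq_a) - set(freq_b))]
            + [{"pair": p, "source": "b", "frequency": freq_b[p]}
               for p in sorted(set(freq_b) - set(freq_a))])
    unshared = pd.DataFrame(rows, columns=["pair", "source", "frequency"])
    return aligned, unshared
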