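"""Self-contained toy systems with the statistical structure of the real
inputs: a rigid multi-helix core with flexible runs, cross-links sampled
from a ground-truth ensemble's contact frequencies (plus decoys), and a
noisy SAXS curve synthesized from known ensemble weights.

The core is a deterministic ideal α-helix bundle (1.5 Å rise and 100° turn
per residue, 2.3 Å helix radius); flexible residues appear in the emitted
structure exactly the way unresolved residues appear in deposited models —
in the sequence, without coordinates. Every 7th residue is designated a
cross-linkable lysine by default, giving realistic restraint sparsity
without sequence modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Ensemble
from .forcefield import CGTopology
from .saxs import SAXSProfile, ensemble_profiles
from .structure_io import Residue, Structure

__all__ = ["ToySpec", "make_toy_complex", "sample_crosslinks",
           "synthesize_saxs", "CrossLinkSample"]


@dataclass
class ToySpec:
    """Recipe for a toy rigid-core/flexible-chain complex.

    ``flexible_chains`` lists (attachment residue in core numbering,
    length); attachment 0 prepends an N-terminal run, attachment equal to
    ``core_size`` appends a C-terminal tail, anything else inserts the run
    after that core residue. The final chain is renumbered consecutively.
    """

    core_size: int = 60
    helix_length: int = 20          # residues per helix in the bundle
    helix_rise: float = 1.5         # Å per residue along the axis
    helix_radius: float = 2.3       # Å
    helix_turn: float = 100.0       # degrees per residue
    bundle_radius: float = 5.5      # Å helix-axis offset from bundle axis
    flexible_chains: list[tuple[int, int]] = field(
        default_factory=lambda: [(60, 20)])
    lysine_interval: int = 7
    n_crosslinks: int = 10
    decoy_fraction: float = 0.2
    saxs_noise: float = 0.01        # relative σ
    true_weights: tuple[float, ...] = (0.6, 0.3, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_size < 1:
            raise ValueError("core_size must be >= 1")
        if any(l < 0 for _, l in self.flexible_chains):
            raise ValueError("flexible chain lengths must be >= 0")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ValueError("decoy_fraction must lie in [0, 1]")
        w = np.asarray(self.true_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("true_weights must be non-negative and sum to 1")


def _helix_bundle(spec: ToySpec) -> np.ndarray:
    """Deterministic Cα coordinates for the core: antiparallel helix bundle."""
    coords = np.empty((spec.core_size, 3))
    per = spec.helix_length
    n_helices = int(np.ceil(spec.core_size / per))
    for idx in range(spec.core_size):
        h, k = divmod(idx, per)
        phi_axis = 2.0 * np.pi * h / max(n_helices, 1)
        cx = spec.bundle_radius * np.cos(phi_axis) if n_helices > 1 else 0.0
        cy = spec.bundle_radius * np.sin(phi_axis) if n_helices > 1 else 0.0
        ang = np.deg2rad(spec.helix_turn) * k
        z = spec.helix_rise * k
        if h % 2 == 1:                      # antiparallel packing
            z = spec.helix_rise * (per - 1) - z
        coords[idx] = (cx + spec.helix_radius * np.cos(ang),
                       cy + spec.helix_radius * np.sin(ang),
                       z)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1.0:
        raise ValueError(f"core geometry degenerate: bead pair at {d.min():.2f} Å")
    return coords


def make_toy_complex(spec: ToySpec) -> tuple[Structure, list[tuple[int, int]]]:
    """Build the toy structure and its flexible-region ranges.

    Returns a single-chain ("A") :class:`Structure` with the core residues
    carrying coordinates and flexible residues absent, plus the list of
    flexible (start, end) residue ranges in the final numbering. The core
    is deterministic — identical specs give identical structures.
    """
    core = _helix_bundle(spec)
    inserts: dict[int, int] = {}
    for attach, length in spec.flexible_chains:
        if not 0 <= attach <= spec.core_size:
            raise ValueError(f"attachment residue {attach} outside core")
        if length > 0:
            inserts[attach] = inserts.get(attach, 0) + length

    residues: list[Residue] = []
    flexible_ranges: list[tuple[int, int]] = []
    number = 0

    def emit_flexible(count: int) -> None:
        nonlocal number
        start = number + 1
        for _ in range(count):
            number += 1
            name = "LYS" if number % spec.lysine_interval == 0 else "ALA"
            residues.append(Residue(number, name, None))
        flexible_ranges.append((start, number))

    if 0 in inserts:
        emit_flexible(inserts[0])
    for core_idx in range(spec.core_size):
        number += 1
        name = "LYS" if number % spec.lysine_interval == 0 else "ALA"
        residues.append(Residue(number, name, core[core_idx].copy()))
        if core_idx + 1 in inserts:
            emit_flexible(inserts[core_idx + 1])

    st = Structure(chains=["A"], residues={"A": residues})
    return st, flexible_ranges


@dataclass
class CrossLinkSample:
    """Sampled cross-link table plus its ground-truth bookkeeping."""

    table: pd.DataFrame                       # xl_analysis CSV schema
    true_pairs: list[tuple[int, int]]         # bead-index pairs
    decoy_pairs: list[tuple[int, int]]

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def sample_crosslinks(ensemble: Ensemble, topology: CGTopology,
                      n_links: int, decoy_fraction: float = 0.0,
                      threshold: float = 25.0, seed: int = 0,
                      min_separation: int = 5,
                      require_flexible: bool = False,
                      max_frequency: float = 1.0) -> CrossLinkSample:
    """Draw cross-links from a ground-truth ensemble's contact frequencies.

    True links come from lysine pairs whose weighted contact frequency is
    ≥ 0.5 at ``threshold``; decoys from pairs with frequency ≤ 0.05.
    Scores are drawn in (60, 100) so everything passes the default
    identification cutoff. Pairs closer than ``min_separation`` residues
    along a chain are excluded as uninformative. ``require_flexible``
    keeps only pairs with at least one flexible endpoint, mirroring data
    sets dominated by links to unresolved regions. ``max_frequency``
    (default 1.0) optionally caps the true-link frequency so benchmarks
    can restrict to links that free dynamics sometimes breaks — links at
    frequency 1.0 are satisfied by any trajectory and probe nothing.
    """
    from .crosslinks import contact_frequency

    if n_links < 1:
        raise ValueError("n_links must be >= 1")
    lys = topology.lysines
    pairs = []
    for a in range(len(lys)):
        for b in range(a + 1, len(lys)):
            i, j = lys[a], lys[b]
            (ca, na), (cb, nb) = topology.keys[i], topology.keys[j]
            if ca == cb and abs(nb - na) < min_separation:
                continue
            if require_flexible and not (topology.flexible[i]
                                         or topology.flexible[j]):
                continue
            pairs.append((i, j))
    if not pairs:
        raise ValueError("no eligible lysine pairs in topology")
    freq = contact_frequency(ensemble, pairs, threshold)
    eligible_true = [p for p, f in zip(pairs, freq)
                     if 0.5 <= f <= max_frequency]
    eligible_decoy = [p for p, f in zip(pairs, freq) if f <= 0.05]

    n_decoy = int(round(n_links * decoy_fraction))
    n_true = n_links - n_decoy
    if len(eligible_true) < n_true or len(eligible_decoy) < n_decoy:
        raise ValueError(
            f"insufficient eligible pairs (true {len(eligible_true)}/{n_true}, "
            f"decoy {len(eligible_decoy)}/{n_decoy}); use a larger ensemble or "
            "a lower threshold")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([seed, 23])))
    true_sel = [eligible_true[k] for k in
                rng.choice(len(eligible_true), size=n_true, replace=False)]
    decoy_sel = [eligible_decoy[k] for k in
                 rng.choice(len(eligible_decoy), size=n_decoy, replace=False)]

    rows = []
    for (i, j) in true_sel + decoy_sel:
        (ca, na), (cb, nb) = topology.keys[i], topology.keys[j]
        rows.append({"protein_a": ca, "residue_a": na,
                     "protein_b": cb, "residue_b": nb,
                     "score": float(rng.uniform(60.0, 100.0))})
    return CrossLinkSample(table=pd.DataFrame(rows), true_pairs=true_sel,
                           decoy_pairs=decoy_sel)


def select_separated_frames(ensemble: Ensemble, q_grid: np.ndarray,
                            n_states: int = 3) -> list[int]:
    """Pick frames with well-separated scattering profiles (greedy max-min).

    Ground-truth states for recovery benchmarks should be distinguishable;
    this picks the two frames with the most different I(0)-normalized
    profiles and then greedily adds the frame farthest from all chosen.
    """
    prof = ensemble_profiles(ensemble.frames, q_grid)
    rel = prof / prof[:, :1]
    d = np.linalg.norm(rel[:, None] - rel[None, :], axis=2)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    chosen = [int(i), int(j)]
    while len(chosen) < n_states:
        mind = np.min(d[chosen], axis=0)
        mind[chosen] = -1.0
        chosen.append(int(np.argmax(mind)))
    return chosen


def synthesize_saxs(ensemble: Ensemble, true_weights: np.ndarray,
                    q_grid: np.ndarray, noise_rel: float = 0.01,
                    seed: int = 0, alpha_true: float = 1.0) -> SAXSProfile:
    """Noisy experimental-style curve from a known weighted mixture.

    I_exp = α_true · Σ_k w_k · I_debye(frame_k) plus Gaussian noise of
    s.d. noise_rel·I; the σ column is noise_rel·I (ones when noise_rel=0,
    so χ against the exact mixture is well defined).
    """
    w = np.asarray(true_weights, dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("true_weights must be non-negative and sum to 1")
    if noise_rel < 0:
        raise ValueError("noise_rel must be >= 0")
    if len(w) != ensemble.n_frames:
        raise ValueError("one weight per ensemble frame required")
    profiles = ensemble_profiles(ensemble.frames, q_grid)
    mixture = alpha_true * (w @ profiles)
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([seed, 31])))
    if noise_rel > 0:
        sigma = noise_rel * mixture
        intensity = mixture + rng.normal(0.0, sigma)
        return SAXSProfile(np.asarray(q_grid, float), intensity, sigma)
    return SAXSProfile(np.asarray(q_grid, float), mixture,
                       np.ones_like(mixture))
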