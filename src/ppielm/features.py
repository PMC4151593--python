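"""Composition/transition/distribution (CTD) descriptors and feature vectors.

Per region of the re-encoded sequence, 63 descriptors are computed:

* composition (7): percentage of each group among the region's residues;
* transition (21): for each unordered group pair (i,j), i<j, the percentage
  of adjacent residue pairs whose groups are {i,j} in either order, out of
  L-1 adjacencies;
* distribution (35): for each group, the 1-based positions (as a percent of
  region length) of the first occurrence and of the occurrences at the 25%,
  50%, 75% and 100% quantiles of that group's occurrence count.  Quantile
  indices use round-half-up of q*c clamped to [1, c].

A protein vector concatenates the 27 region blocks (1701 values) with the
20-dimensional global amino-acid composition (fractions, alphabetical by
one-letter code) for 1721 values; a pair vector concatenates two protein
vectors (A then B) for 3442.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import N_GROUPS, GroupSequence, Policy, encode
from .regions import RegionScheme, enumerate_regions, segment_boundaries, slice_region
from .sequence_io import PairRecord, ProteinRecord

#: Standard amino acids, alphabetical by one-letter code (global AAC order).
AAC_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Unordered group pairs (i,j), i<j, lexicographic — the transition order.
TRANSITION_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(1, N_GROUPS + 1) for j in range(i + 1, N_GROUPS + 1)
)

QUANTILES = (0.0, 0.25, 0.50, 0.75, 1.0)

N_BLOCK = N_GROUPS + len(TRANSITION_PAIRS) + N_GROUPS * len(QUANTILES)  # 63

# flat index of unordered pair (lo,hi) in TRANSITION_PAIRS
_PAIR_INDEX = np.full((N_GROUPS + 1, N_GROUPS + 1), -1, dtype=np.int64)
for _k, (_i, _j) in enumerate(TRANSITION_PAIRS):
    _PAIR_INDEX[_i, _j] = _k


def composition(fragment: np.ndarray) -> np.ndarray:
    """Percent of each group (1..7) among the fragment's symbols."""
    fragment = np.asarray(fragment)
    if fragment.size == 0:
        raise ValueError("composition of an empty fragment is undefined")
    counts = np.bincount(fragment, minlength=N_GROUPS + 1)[1:]
    return 100.0 * counts / fragment.size


def transition(fragment: np.ndarray) -> np.ndarray:
    """Percent of adjacent symbol pairs falling in each unordered group
    pair (i,j), i<j, out of the L-1 adjacencies."""
    fragment = np.asarray(fragment)
    if fragment.size < 2:
        raise ValueError("transition needs a fragment of length >= 2")
    a, b = fragment[:-1], fragment[1:]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    hetero = lo != hi
    idx = _PAIR_INDEX[lo[hetero], hi[hetero]]
    counts = np.bincount(idx, minlength=len(TRANSITION_PAIRS))
    return 100.0 * counts / (fragment.size - 1)


def _quantile_index(q: float, c: int) -> int:
    # round-half-up of q*c, clamped to [1, c]
    return min(max(int(np.floor(q * c + 0.5)), 1), c)


def distribution(fragment: np.ndarray) -> np.ndarray:
    """For each group, positions (percent of fragment length) of its first
    occurrence and of the 25/50/75/100% quantile occurrences; absent groups
    yield five zeros."""
    fragment = np.asarray(fragment)
    if fragment.size == 0:
        raise ValueError("distribution of an empty fragment is undefined")
    L = fragment.size
    out = np.zeros(N_GROUPS * len(QUANTILES))
    for g in range(1, N_GROUPS + 1):
        positions = np.flatnonzero(fragment == g) + 1  # 1-based
        c = positions.size
        if c == 0:
            continue
        ks = [1 if q == 0.0 else _quantile_index(q, c) for q in QUANTILES]
        out[(g - 1) * len(QUANTILES):g * len(QUANTILES)] = (
            100.0 * positions[np.array(ks) - 1] / L
        )
    return out


def region_block(fragment: np.ndarray) -> np.ndarray:
    """The 63 descriptors of one region: [C(7), T(21), D(35)]."""
    return np.concatenate([composition(fragment), transition(fragment),
                           distribution(fragment)])


def global_aac(sequence: str) -> np.ndarray:
    """Global amino-acid composition: fraction of each of the 20 standard
    residues, alphabetical by one-letter code.  Nonstandard residues are
    ignored in the numerator but counted in the denominator only if
    standard — i.e. fractions are over standard residues present."""
    seq = sequence.upper()
    counts = np.array([seq.count(a) for a in AAC_ALPHABET], dtype=np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence contains no standard residues")
    return counts / total


@dataclass(frozen=True)
class ProteinFeatureVector:
    """Per-protein representation: 27 region CTD blocks then global AAC."""

    protein_id: str
    values: np.ndarray  # length 27*63 + 20 = 1721 for the 7-segment scheme


@dataclass(frozen=True)
class PairFeatureVector:
    """Per-pair representation: protein A's vector then protein B's."""

    id_a: str
    id_b: str
    values: np.ndarray  # length 3442 for the 7-segment scheme
    label: str | None = None


def protein_vector(record: ProteinRecord | GroupSequence,
                   scheme: RegionScheme | None = None,
                   policy: Policy = "reject") -> ProteinFeatureVector:
    """Compute the full per-protein vector (local CTD blocks + global AAC).

    Requires every region fragment to have length >= 2, i.e. sequence
    length >= 2 * n_segments.
    """
    if scheme is None:
        scheme = enumerate_regions()
    if isinstance(record, GroupSequence):
        gs = record
        sequence = None
    else:
        gs = encode(record, policy=policy)
        sequence = record.sequence
    if gs.length < 2 * scheme.n_segments:
        raise ValueError(
            f"{gs.protein_id!r}: length {gs.length} too short — every region "
            f"needs >= 2 symbols (single-segment region of a "
            f"{scheme.n_segments}-segment split)"
        )
    boundaries = segment_boundaries(gs.length, scheme.n_segments)
    blocks = [region_block(slice_region(gs, boundaries, region))
              for region in scheme.regions]
    if sequence is None:
        raise ValueError("global AAC requires the raw amino-acid sequence")
    values = np.concatenate(blocks + [global_aac(sequence)])
    return ProteinFeatureVector(gs.protein_id, values)


def pair_vector(a: ProteinFeatureVector, b: ProteinFeatureVector,
                label: str | None = None) -> PairFeatureVector:
    """Concatenate two protein vectors (A then B)."""
    if a.values.shape != b.values.shape:
        raise ValueError(
            f"feature length mismatch: {a.values.size} vs {b.values.size}"
        )
    return PairFeatureVector(a.protein_id, b.protein_id,
                             np.concatenate([a.values, b.values]), label)


def feature_names(scheme: RegionScheme | None = None) -> list[str]:
    """Systematic per-protein column names, e.g. ``region1-2.T.1-3``."""
    if scheme is None:
        scheme = enumerate_regions()
    names: list[str] = []
    for start, end in scheme.regions:
        prefix = f"region{start}-{end}"
        names += [f"{prefix}.C.{g}" for g in range(1, N_GROUPS + 1)]
        names += [f"{prefix}.T.{i}-{j}" for i, j in TRANSITION_PAIRS]
        names += [f"{prefix}.D.{g}.q{int(q * 100)}"
                  for g in range(1, N_GROUPS + 1) for q in QUANTILES]
    names += [f"aac.{a}" for a in AAC_ALPHABET]
    return names


def featurize_proteins(records: Iterable[ProteinRecord],
                       scheme: RegionScheme | None = None,
                       policy: Policy = "reject",
                       ) -> dict[str, ProteinFeatureVector]:
    """Per-protein vectors keyed by id."""
    if scheme is None:
        scheme = enumerate_regions()
    return {r.id: protein_vector(r, scheme, policy) for r in records}


def pair_matrix(pairs: Sequence[PairRecord],
                vectors: Mapping[str, ProteinFeatureVector],
                ) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair vectors into an (n_pairs, 3442) matrix plus a 0/1 label
    array (1 = interacting; unknown labels become 0 only if present —
    prefer labeled input for training)."""
    missing = {p.id_a for p in pairs if p.id_a not in vectors} | \
              {p.id_b for p in pairs if p.id_b not in vectors}
    if missing:
        raise KeyError(f"no feature vectors for proteins: {sorted(missing)[:5]}...")
    X = np.stack([
        np.concatenate([vectors[p.id_a].values, vectors[p.id_b].values])
        for p in pairs
    ])
    y = np.array([1 if p.label == "interacting" else 0 for p in pairs])
    return X, y


def write_feature_tsv(pairs: Sequence[PairRecord], X: np.ndarray,
                      path: str | Path,
                      scheme: RegionScheme | None = None) -> None:
    """Export a pair feature matrix as TSV with systematic column names."""
    per_protein = feature_names(scheme)
    cols = [f"a.{c}" for c in per_protein] + [f"b.{c}" for c in per_protein]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "id_a", [p.id_a for p in pairs])
    df.insert(1, "id_b", [p.id_b for p in pairs])
    df.to_csv(path, sep="\t", index=False)
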