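"""Synthetic proteins and labeled interaction pairs with planted signal.

The generator emulates the statistical structure the feature pipeline
assumes: each protein belongs to a latent interaction class with its own
amino-acid composition profile and to a subcellular compartment; residues
are drawn i.i.d. from a mixture of the uniform profile and the class
profile weighted by ``signal_strength``.  A symmetric class-compatibility
matrix (fixed by the seed) plants the interaction rule: positive pairs join
compatible classes, negative pairs join incompatible classes in different
compartments, so the labels are detectable from composition features alone
and vanish as ``signal_strength`` goes to 0.

Defaults (600 proteins, lengths 50-2000 over six compartments, 1,000
positive + 1,000 negative pairs) run the full cross-validated pipeline in
well under a minute.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import AAC_ALPHABET
from .sequence_io import (PairRecord, ProteinRecord, write_annotations,
                          write_fasta, write_pairs)


@dataclass
class SyntheticConfig:
    n_proteins: int = 600
    length_range: tuple[int, int] = (50, 2000)
    n_compartments: int = 6
    n_classes: int = 3
    composition_bias: np.ndarray | None = None  # (n_classes, 20) profiles
    signal_strength: float = 1.0
    n_positive_pairs: int = 1000
    n_negative_pairs: int = 1000
    seed: int = 0
    # fractions of records given filter-triggering annotations
    frac_fragment: float = 0.0
    frac_multi_location: float = 0.0
    frac_uncertain: float = 0.0

    def __post_init__(self) -> None:
        if self.length_range[0] < 14:
            raise ValueError("minimum length must be >= 14 (2 x 7 segments)")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.composition_bias is not None:
            profiles = np.asarray(self.composition_bias, dtype=np.float64)
            if profiles.shape != (self.n_classes, 20):
                raise ValueError("composition_bias must be (n_classes, 20)")
            if np.any(profiles < 0) or not np.allclose(profiles.sum(axis=1), 1.0):
                raise ValueError("class profiles must be probability "
                                 "distributions over the 20 letters")
            self.composition_bias = profiles


def class_profiles(cfg: SyntheticConfig) -> np.ndarray:
    """Per-class residue profiles: configured, or Dirichlet(0.5) draws
    (sparse enough that classes are clearly separated in composition)."""
    if cfg.composition_bias is not None:
        return cfg.composition_bias
    rng = np.random.default_rng(cfg.seed)
    return rng.dirichlet(np.full(20, 0.5), size=cfg.n_classes)


def compatibility_matrix(cfg: SyntheticConfig) -> np.ndarray:
    """Symmetric boolean class-compatibility matrix, fixed by the seed;
    guaranteed to contain at least one compatible and one incompatible
    unordered class pair."""
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_classes
    while True:
        upper = rng.integers(0, 2, size=(n, n)).astype(bool)
        compat = np.triu(upper) | np.triu(upper, 1).T
        vals = compat[np.triu_indices(n)]
        if vals.any() and not vals.all():
            return compat


def generate_proteins(cfg: SyntheticConfig) -> list[ProteinRecord]:
    """Draw proteins with latent classes, compartments and annotations.

    Residues are i.i.d. from (1 - s) * uniform + s * class_profile where
    s is ``signal_strength``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    profiles = class_profiles(cfg)
    uniform = np.full(20, 1 / 20)
    letters = np.array(list(AAC_ALPHABET))
    records: list[ProteinRecord] = []
    for i in range(cfg.n_proteins):
        cls = int(rng.integers(cfg.n_classes))
        compartment = f"compartment{int(rng.integers(cfg.n_compartments)) + 1}"
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        mix = (1 - cfg.signal_strength) * uniform + cfg.signal_strength * profiles[cls]
        seq = "".join(letters[rng.choice(20, size=length, p=mix)])
        records.append(ProteinRecord(
            id=f"SYN{i:05d}",
            sequence=seq,
            location=compartment,
            is_fragment=bool(rng.random() < cfg.frac_fragment),
            location_uncertain=bool(rng.random() < cfg.frac_uncertain),
            n_locations=2 if rng.random() < cfg.frac_multi_location else 1,
            latent_class=cls,
        ))
    return records


def generate_pairs(proteins: list[ProteinRecord],
                   cfg: SyntheticConfig) -> list[PairRecord]:
    """Sample labeled pairs under the planted rule.

    Positives join proteins of compatible latent classes; negatives join
    incompatible classes across different compartments.  The two sets are
    disjoint as unordered pairs.
    """
    if any(p.latent_class is None or p.location is None for p in proteins):
        raise ValueError("proteins must carry latent classes and compartments")
    rng = np.random.default_rng(cfg.seed + 3)
    compat = compatibility_matrix(cfg)
    n = len(proteins)
    classes = np.array([p.latent_class for p in proteins])
    locations = np.array([p.location for p in proteins])
    ids = [p.id for p in proteins]

    seen: set[frozenset[str]] = set()

    def sample(count: int, want_positive: bool, label: str) -> list[PairRecord]:
        out: list[PairRecord] = []
        attempts = 0
        max_attempts = 2000 * count + 10000
        while len(out) < count:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"could not draw {count} {label} pairs; configuration "
                    "infeasible (too few admissible pairs)"
                )
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            compatible = bool(compat[classes[i], classes[j]])
            if want_positive and not compatible:
                continue
            if not want_positive and (compatible or locations[i] == locations[j]):
                continue
            key = frozenset((ids[i], ids[j]))
            if key in seen:
                continue
            seen.add(key)
            out.append(PairRecord(ids[i], ids[j], label))
        return out

    positives = sample(cfg.n_positive_pairs, True, "interacting")
    negatives = sample(cfg.n_negative_pairs, False, "non-interacting")
    return positives + negatives


def generate_dataset(cfg: SyntheticConfig
                     ) -> tuple[list[ProteinRecord], list[PairRecord]]:
    proteins = generate_proteins(cfg)
    return proteins, generate_pairs(proteins, cfg)


def write_dataset(proteins: list[ProteinRecord], pairs: list[PairRecord],
                  outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + labeled pairs TSV + annotation TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "pairs": outdir / "pairs.tsv",
        "annotations": outdir / "annotations.tsv",
    }
    write_fasta(proteins, paths["fasta"])
    write_pairs(pairs, paths["pairs"], labeled=True)
    write_annotations(proteins, paths["annotations"])
    return paths
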