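"""Reading, writing and filtering of protein sequence and pair data.

Sequences travel as FASTA (any line wrapping), interaction pairs as 2- or
3-column delimited text, and optional per-protein annotations (subcellular
location, fragment flag, location multiplicity/uncertainty) as a TSV with a
header.  The filtering rules implemented here mirror the construction of a
non-interacting "gold negative" set from an annotated protein database:
drop uncertain or multiple subcellular locations, fragments, and sequences
shorter than 50 residues, then pair proteins across compartments.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Minimum sequence length retained when building negative candidates.
MIN_NEGATIVE_LENGTH = 50

Label = Literal["interacting", "non-interacting", "unknown"]


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input."""


@dataclass
class ProteinRecord:
    """A protein sequence plus the annotations the negative-set filters use.

    ``latent_class`` is populated only by the synthetic generator; real data
    never carries it.
    """

    id: str
    sequence: str
    location: str | None = None
    is_fragment: bool | None = None
    location_uncertain: bool | None = None
    n_locations: int | None = None
    latent_class: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")


@dataclass(frozen=True)
class PairRecord:
    """An unordered protein pair with an interaction label."""

    id_a: str
    id_b: str
    label: Label = "unknown"

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError(f"self-pair not allowed: {self.id_a!r}")

    @property
    def key(self) -> frozenset[str]:
        """Order-insensitive identity of the pair."""
        return frozenset((self.id_a, self.id_b))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The id is the header token before the first whitespace; sequences are
    uppercased with whitespace stripped.  Duplicate ids and sequence data
    appearing before the first header are errors.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as multi-FASTA (wrapped at 60 columns)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def _detect_delimiter(line: str) -> str:
    # tab preferred, comma fallback
    return "\t" if "\t" in line else ","


def read_pairs(path: str | Path, labeled: bool = True) -> list[PairRecord]:
    """Read a 2-column (unlabeled) or 3-column (labeled, third column 0/1)
    pair list.  Duplicate unordered pairs and self-pairs are dropped with a
    logged count."""
    path = Path(path)
    expected_cols = 3 if labeled else 2
    pairs: list[PairRecord] = []
    seen: set[frozenset[str]] = set()
    n_dup = n_self = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split(_detect_delimiter(line))
            if len(fields) != expected_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {expected_cols} columns, "
                    f"got {len(fields)}"
                )
            id_a, id_b = fields[0].strip(), fields[1].strip()
            if labeled:
                lab_raw = fields[2].strip()
                if lab_raw not in {"0", "1"}:
                    raise ValueError(
                        f"{path}:{lineno}: label must be 0 or 1, got {lab_raw!r}"
                    )
                label: Label = "interacting" if lab_raw == "1" else "non-interacting"
            else:
                label = "unknown"
            if id_a == id_b:
                n_self += 1
                continue
            key = frozenset((id_a, id_b))
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            pairs.append(PairRecord(id_a, id_b, label))
    if n_self or n_dup:
        logger.info(
            "read_pairs(%s): dropped %d self-pair(s) and %d duplicate pair(s)",
            path, n_self, n_dup,
        )
    return pairs


def write_pairs(pairs: Iterable[PairRecord], path: str | Path,
                labeled: bool = True) -> None:
    """Write pairs as TSV; labeled output maps interacting→1, other→0."""
    with open(path, "w") as fh:
        for p in pairs:
            if labeled:
                fh.write(f"{p.id_a}\t{p.id_b}\t{1 if p.label == 'interacting' else 0}\n")
            else:
                fh.write(f"{p.id_a}\t{p.id_b}\n")


_ANNOTATION_COLUMNS = ["id", "location", "fragment", "n_locations",
                       "location_uncertain"]


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the optional annotation TSV (columns id, location, fragment,
    n_locations, location_uncertain)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    return df


def write_annotations(records: Iterable[ProteinRecord], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "location": r.location if r.location is not None else "",
            "fragment": int(bool(r.is_fragment)) if r.is_fragment is not None else "",
            "n_locations": r.n_locations if r.n_locations is not None else "",
            "location_uncertain": (
                int(bool(r.location_uncertain))
                if r.location_uncertain is not None else ""
            ),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def attach_annotations(records: Sequence[ProteinRecord],
                       annotations: pd.DataFrame) -> list[ProteinRecord]:
    """Return copies of ``records`` with annotation fields filled from the table."""

    def _opt_bool(v) -> bool | None:
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return bool(int(v))

    def _opt_int(v) -> int | None:
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return int(v)

    table = annotations.set_index("id")
    out = []
    for rec in records:
        if rec.id not in table.index:
            out.append(rec)
            continue
        row = table.loc[rec.id]
        loc = row["location"]
        out.append(replace(
            rec,
            location=None if (isinstance(loc, float) and np.isnan(loc)) or loc == ""
            else str(loc),
            is_fragment=_opt_bool(row["fragment"]),
            n_locations=_opt_int(row["n_locations"]),
            location_uncertain=_opt_bool(row["location_uncertain"]),
        ))
    return out


def filter_negative_candidates(records: Iterable[ProteinRecord],
                               strict: bool = False) -> list[ProteinRecord]:
    """Apply the four negative-candidate criteria in order: drop uncertain
    location, multiple locations, fragments, and sequences shorter than 50
    residues.

    In lenient mode (default) a missing annotation passes its criterion —
    only length is always checkable.  In strict mode a missing annotation
    fails it.
    """
    kept = []
    dropped = {"uncertain": 0, "multi_location": 0, "fragment": 0, "short": 0}

    def fails(value: bool | None, bad: bool) -> bool:
        if value is None:
            return strict
        return value is bad

    for rec in records:
        if fails(rec.location_uncertain, True):
            dropped["uncertain"] += 1
        elif (rec.n_locations is None and strict) or (
                rec.n_locations is not None and rec.n_locations > 1):
            dropped["multi_location"] += 1
        elif fails(rec.is_fragment, True):
            dropped["fragment"] += 1
        elif len(rec.sequence) < MIN_NEGATIVE_LENGTH:
            dropped["short"] += 1
        else:
            kept.append(rec)
    logger.info("filter_negative_candidates: kept %d, dropped %s", len(kept), dropped)
    return kept


def count_cross_compartment_pairs(records: Sequence[ProteinRecord]) -> int:
    """Number of distinct unordered pairs joining two different compartments."""
    sizes = pd.Series([r.location for r in records]).value_counts()
    n = int(sizes.sum())
    within = int((sizes * (sizes - 1) // 2).sum())
    return n * (n - 1) // 2 - within


def build_negative_pairs(records: Sequence[ProteinRecord], n_pairs: int,
                         rng_seed: int) -> list[PairRecord]:
    """Randomly pair proteins from separate subcellular compartments.

    Produces ``n_pairs`` distinct unordered cross-compartment pairs labeled
    non-interacting; deterministic for a fixed seed.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be positive")
    recs = [r for r in records if r.location is not None]
    compartments = {r.location for r in recs}
    if len(compartments) < 2:
        raise ValueError("need proteins from at least two compartments")
    available = count_cross_compartment_pairs(recs)
    if n_pairs > available:
        raise ValueError(
            f"requested {n_pairs} pairs but only {available} distinct "
            "cross-compartment pairs exist"
        )
    rng = np.random.default_rng(rng_seed)
    ids = [r.id for r in recs]
    locs = [r.location for r in recs]

    if n_pairs > available // 2:
        # dense request: enumerate all admissible pairs and subsample
        all_pairs = [
            (i, j)
            for i, j in itertools.combinations(range(len(recs)), 2)
            if locs[i] != locs[j]
        ]
        chosen = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        return [
            PairRecord(ids[all_pairs[k][0]], ids[all_pairs[k][1]], "non-interacting")
            for k in sorted(chosen)
        ]

    seen: set[frozenset[str]] = set()
    out: list[PairRecord] = []
    while len(out) < n_pairs:
        i, j = rng.integers(0, len(recs), size=2)
        if i == j or locs[i] == locs[j]:
            continue
        key = frozenset((ids[i], ids[j]))
        if key in seen:
            continue
        seen.add(key)
        out.append(PairRecord(ids[i], ids[j], "non-interacting"))
    return out
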