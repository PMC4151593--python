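"""Reduced seven-group amino-acid alphabet.

The 20 standard residues are clustered into seven groups by side-chain
dipole and volume (the conjoint-triad grouping): {A,G,V} {I,L,F,P}
{Y,M,T,S} {H,N,Q,W} {R,K} {D,E} {C}.  A sequence is re-encoded by replacing
each residue with its 1-based group index, e.g. ``CCYGGGYYCYYYCGGCCYYCG``
becomes ``773111337333711773371``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .sequence_io import ProteinRecord

logger = logging.getLogger(__name__)

N_GROUPS = 7

#: Side-chain dipole/volume grouping of the 20 standard amino acids.
GROUP_OF: dict[str, int] = {
    **dict.fromkeys("AGV", 1),
    **dict.fromkeys("ILFP", 2),
    **dict.fromkeys("YMTS", 3),
    **dict.fromkeys("HNQW", 4),
    **dict.fromkeys("RK", 5),
    **dict.fromkeys("DE", 6),
    "C": 7,
}

#: Nonstandard residues under the "map" policy: selenocysteine and
#: pyrrolysine to the group of their closest standard residue, ambiguity
#: codes to the group shared by (or typical of) their possibilities.
#: X carries no group information and is dropped with a warning.
_NONSTANDARD_MAP = {"U": 7, "B": 6, "Z": 6, "J": 2, "O": 5}

Policy = Literal["reject", "map"]


@dataclass(frozen=True)
class GroupSequence:
    """A protein sequence over the 7-letter group alphabet."""

    protein_id: str
    symbols: np.ndarray  # int8 array of group indices, 1..7

    def __post_init__(self) -> None:
        if self.symbols.size == 0:
            raise ValueError(f"{self.protein_id!r}: empty group sequence")

    @property
    def length(self) -> int:
        return int(self.symbols.size)


def encode(record: ProteinRecord | str, policy: Policy = "reject") -> GroupSequence:
    """Re-encode a protein sequence over the seven-group alphabet.

    Under ``reject`` (default, training-grade data) any residue outside the
    20 standard letters raises, naming position and residue.  Under ``map``,
    U/B/Z/J/O are mapped to the group of their nearest standard residue and
    X is dropped with a logged warning.
    """
    if isinstance(record, str):
        record = ProteinRecord(id="<anonymous>", sequence=record)
    symbols: list[int] = []
    n_dropped = 0
    for pos, residue in enumerate(record.sequence.upper(), start=1):
        group = GROUP_OF.get(residue)
        if group is None:
            if policy == "reject":
                raise ValueError(
                    f"{record.id!r}: nonstandard residue {residue!r} at "
                    f"position {pos}"
                )
            group = _NONSTANDARD_MAP.get(residue)
            if group is None:
                n_dropped += 1
                continue
        symbols.append(group)
    if n_dropped:
        logger.warning("%s: dropped %d unknown residue(s) under map policy",
                       record.id, n_dropped)
    if not symbols:
        raise ValueError(f"{record.id!r}: no encodable residues")
    return GroupSequence(record.id, np.asarray(symbols, dtype=np.int8))
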