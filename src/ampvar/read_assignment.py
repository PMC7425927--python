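"""Assign collapsed sequences to amplicons via primer signatures.

After index cleaning every collapsed key begins at its amplicon's
forward primer, so reading the catalog's selected positions off the key
yields a signature that identifies the amplicon directly — no alignment
needed for demultiplexing.  Matching is exact by default; a sequencing
variant sitting exactly on a signature position would mis-route the key,
and an optional rescue pass re-examines unassigned keys by aligning
their primer region against every forward primer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .banded_alignment import align_local, is_local_optimal
from .io_formats import AmpliconPanel
from .pair_collapse import CollapsedSequence
from .primer_features import FeatureCatalog

__all__ = ["AssignedSequence", "extract_signature", "assign"]


@dataclass
class AssignedSequence:
    """A collapsed key with its amplicon label (``None`` when unassigned)."""

    collapsed: CollapsedSequence
    amplicon_id: str | None
    matched_signature: str = ""


def extract_signature(seq: str, positions: Sequence[int]) -> str | None:
    """Characters of ``seq`` at the selected 1-based positions.

    Returns ``None`` when the sequence is too short to cover every
    position.
    """
    if not positions:
        return ""
    if len(seq) < max(positions):
        return None
    return "".join(seq[p - 1] for p in positions)


def _rescue(
    seq: str, panel: AmpliconPanel, k_max: int
) -> str | None:
    """Best-primer fallback for keys that miss every exact signature.

    Aligns the key's leading region against each forward primer and
    assigns to the unique primer with the smallest ``k`` not exceeding
    ``k_max``.  Ties are left unassigned rather than guessed.
    """
    best_k: int | None = None
    best_ids: list[str] = []
    for amp in panel:
        window = seq[: len(amp.fwd_primer) + 4]
        if not window:
            continue
        result = align_local(amp.fwd_primer, window, len(window))
        if not is_local_optimal(result, k_max):
            continue
        if best_k is None or result.k < best_k:
            best_k, best_ids = result.k, [amp.amplicon_id]
        elif result.k == best_k:
            best_ids.append(amp.amplicon_id)
    return best_ids[0] if len(best_ids) == 1 else None


def assign(
    collapsed: Iterable[CollapsedSequence],
    catalog: FeatureCatalog,
    *,
    rescue: bool = False,
    panel: AmpliconPanel | None = None,
    k_max: int = 2,
) -> list[AssignedSequence]:
    """Label each collapsed key with its amplicon, or leave it unassigned.

    Every key is assigned to exactly one amplicon (signatures are
    injective) or carried through unassigned — never silently dropped.
    With ``rescue=True`` (requires ``panel``) unassigned keys get the
    alignment fallback described in :func:`_rescue`.
    """
    if rescue and panel is None:
        raise ValueError("rescue mode needs the panel's primers")
    by_signature = {sig: amp for amp, sig in catalog.signatures.items()}
    if len(by_signature) != len(catalog.signatures):
        raise ValueError("catalog signatures are not injective")
    out: list[AssignedSequence] = []
    for cs in collapsed:
        sig = extract_signature(cs.spliced_seq, catalog.selected_positions)
        amp_id = by_signature.get(sig) if sig is not None else None
        if amp_id is None and rescue and panel is not None:
            amp_id = _rescue(cs.spliced_seq, panel, k_max)
            sig = catalog.signatures.get(amp_id, "") if amp_id else sig
        out.append(
            AssignedSequence(
                collapsed=cs,
                amplicon_id=amp_id,
                matched_signature=sig if (amp_id and sig) else "",
            )
        )
    return out
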