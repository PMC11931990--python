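"""Interface contact-pair analysis and conservation lookup.

Cross-protein residue pairs whose minimum interatomic distance falls below a
cutoff (3 Å by default) define the docking interface.  Contact residues are
then merged into sequence regions — stretches on one chain whose consecutive
members are close in sequence — while isolated residues are reported
separately; in this system the isolated residues (e.g. Agp2 Arg83) are the
candidates for specifically evolved interactions, which motivates the
conservation check across an alignment of homologs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.spatial import cKDTree

from .exceptions import InvalidArgumentError
from .structure_io import DEFAULT_CHAIN_MAP, StructureModel

#: Contact cutoff in Å.
DEFAULT_CUTOFF = 3.0
#: Two contact residues on one chain merge into a region when at most this
#: many non-contact residues lie between them.
DEFAULT_GAP_THRESHOLD = 15


@dataclass(frozen=True)
class ContactPair:
    """One cross-protein residue contact: (name, number, chain) per side."""

    agp1_residue: tuple
    agp2_residue: tuple
    min_distance: float


@dataclass(frozen=True)
class ContactGroup:
    """A run of contact residues on one chain of one protein."""

    protein: str
    chain: str
    first: int
    last: int
    members: tuple  # residue numbers, sorted


def find_contacts(
    model: StructureModel,
    chain_map: Mapping[str, Sequence[str]] = DEFAULT_CHAIN_MAP,
    cutoff: float = DEFAULT_CUTOFF,
    include_hydrogens: bool = False,
) -> list:
    """All cross-protein residue pairs within ``cutoff`` Å.

    The per-pair distance is the minimum over atoms (heavy atoms by default;
    published per-pair distances below ~2 Å suggest a different atom
    selection was used there, so ``include_hydrogens`` is exposed rather
    than silently emulated).  One ContactPair per residue pair, sorted by
    Agp1 residue number.
    """
    for protein in ("agp1", "agp2"):
        if not chain_map.get(protein):
            raise InvalidArgumentError(f"chain map has no chains for {protein}")

    atoms = model.atoms
    if not include_hydrogens:
        atoms = atoms[~atoms["atom_name"].str.lstrip("0123456789").str.startswith("H")]

    def side(protein):
        sub = atoms[atoms["chain_id"].isin(chain_map[protein])]
        xyz = sub[["x", "y", "z"]].to_numpy(dtype=float)
        keys = list(
            zip(sub["residue_name"], sub["residue_number"].astype(int), sub["chain_id"])
        )
        return xyz, keys

    xyz1, keys1 = side("agp1")
    xyz2, keys2 = side("agp2")
    if len(xyz1) == 0 or len(xyz2) == 0:
        return []

    pairs = cKDTree(xyz1).query_ball_tree(cKDTree(xyz2), r=cutoff)
    best: dict = {}
    for i, js in enumerate(pairs):
        if not js:
            continue
        d = np.linalg.norm(xyz2[js] - xyz1[i], axis=1)
        for j, dist in zip(js, d):
            key = (keys1[i], keys2[j])
            if dist <= cutoff and (key not in best or dist < best[key]):
                best[key] = float(dist)
    contacts = [
        ContactPair(agp1_residue=k1, agp2_residue=k2, min_distance=d)
        for (k1, k2), d in best.items()
    ]
    contacts.sort(key=lambda c: (c.agp1_residue[1], c.agp1_residue[2], c.agp2_residue[1]))
    return contacts


def contacts_to_frame(contacts: Sequence[ContactPair]) -> pd.DataFrame:
    """Contact table: Agp1 name/number/chain, Agp2 name/number/chain, distance."""
    return pd.DataFrame(
        [
            {
                "agp1_name": c.agp1_residue[0],
                "agp1_number": c.agp1_residue[1],
                "agp1_chain": c.agp1_residue[2],
                "agp2_name": c.agp2_residue[0],
                "agp2_number": c.agp2_residue[1],
                "agp2_chain": c.agp2_residue[2],
                "distance": c.min_distance,
            }
            for c in contacts
        ]
    )


def group_contacts(
    contacts: Sequence[ContactPair],
    protein: str,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
):
    """Merge one protein's contact residues into sequence regions.

    Residues on the same chain merge into one group when at most
    ``gap_threshold`` non-contact residues separate consecutive sorted
    members (threshold 0 keeps only runs of consecutive numbers).  Returns
    ``(groups, solo_residues)``: multi-member ContactGroups and the
    singleton (chain, residue) pairs.
    """
    if protein not in ("agp1", "agp2"):
        raise InvalidArgumentError(f"protein must be agp1 or agp2, got {protein!r}")
    residues = set()
    for c in contacts:
        _name, resnum, chain = c.agp1_residue if protein == "agp1" else c.agp2_residue
        residues.add((chain, resnum))
    by_chain: dict = {}
    for chain, resnum in sorted(residues):
        by_chain.setdefault(chain, []).append(resnum)

    groups, solo = [], []
    for chain in sorted(by_chain):
        nums = sorted(by_chain[chain])
        run = [nums[0]]
        for n in nums[1:]:
            if n - run[-1] - 1 <= gap_threshold:
                run.append(n)
            else:
                _emit(groups, solo, protein, chain, run)
                run = [n]
        _emit(groups, solo, protein, chain, run)
    return groups, solo


def _emit(groups, solo, protein, chain, run):
    if len(run) == 1:
        solo.append((chain, run[0]))
    else:
        groups.append(
            ContactGroup(protein=protein, chain=chain, first=run[0], last=run[-1],
                         members=tuple(run))
        )


def read_msa_fasta(path) -> dict:
    """Aligned FASTA -> ordered {sequence id: aligned sequence} mapping."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise InvalidArgumentError(f"{path}: no sequences found")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise InvalidArgumentError(f"{path}: sequences have differing aligned lengths")
    return records


def conservation_column(msa: Mapping[str, str], ref_id: str, ref_position: int) -> dict:
    """Residue of every sequence at the column homologous to a reference position.

    ``ref_position`` is 1-based in the ungapped reference sequence; it is
    mapped through the reference gaps to an alignment column and each
    sequence's residue (or '-') at that column is returned.
    """
    if ref_id not in msa:
        raise InvalidArgumentError(f"reference sequence {ref_id!r} not in alignment")
    ref = msa[ref_id]
    if ref_position < 1:
        raise InvalidArgumentError("ref_position must be >= 1")
    count = 0
    column = None
    for col, aa in enumerate(ref):
        if aa != "-":
            count += 1
            if count == ref_position:
                column = col
                break
    if column is None:
        raise InvalidArgumentError(
            f"ref_position {ref_position} beyond ungapped reference length {count}"
        )
    return {seq_id: seq[column] for seq_id, seq in msa.items()}
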