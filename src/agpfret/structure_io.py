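"""Coordinate I/O, label-site resolution and donor-acceptor distance matrices.

Candidate poses of the Agp1·Agp2 complex arrive as PDB files holding two
homodimers (four chains).  The fluorophore attachment point of each label
site is approximated by the Cβ atom of the labeled residue — a few Å from
the true dye position, with no linker correction attempted.  Which chains
belong to which protein is always explicit configuration, never inferred
from sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBIO, PDBParser, StructureBuilder
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .exceptions import FormatError, InvalidArgumentError, MissingSiteError

logger = logging.getLogger(__name__)

#: Agp1 acceptor attachment positions (construct numbering of the mutants).
AGP1_LABEL_POSITIONS = (122, 362, 517, 535, 554, 603)
#: Agp2 donor attachment positions (wild-type cysteines, Cys13 excluded).
AGP2_LABEL_POSITIONS = (29, 33, 47, 249, 277, 353, 647)

#: Default chain-to-protein mapping: A,B = Agp1 dimer; C,D = Agp2 dimer.
DEFAULT_CHAIN_MAP = {"agp1": ("A", "B"), "agp2": ("C", "D")}


@dataclass(frozen=True)
class LabelSite:
    """One fluorophore attachment point."""

    protein: str  # {"agp1", "agp2"}
    chain_id: str
    residue_number: int
    role: str  # {"donor", "acceptor"}
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.protein not in ("agp1", "agp2"):
            raise InvalidArgumentError(f"protein must be agp1 or agp2, got {self.protein!r}")
        if self.role not in ("donor", "acceptor"):
            raise InvalidArgumentError(f"role must be donor or acceptor, got {self.role!r}")
        if self.residue_number < 1:
            raise InvalidArgumentError("residue_number must be >= 1")
        if self.weight < 0:
            raise InvalidArgumentError("weight must be >= 0")

    @property
    def site_id(self) -> str:
        return f"{self.protein}:{self.chain_id}:{self.residue_number}"


@dataclass(frozen=True)
class LabelingScheme:
    """Donor and acceptor site lists with occupancy weights.

    The default emulates the experimental labeling: one donor per Agp2 dimer
    distributed uniformly over the 14 cysteine sites (7 positions x 2
    chains), and one acceptor per Agp1 monomer at the mutated position.
    """

    donor_sites: tuple
    acceptor_sites: tuple
    donors_per_dimer: int = 1
    acceptors_per_dimer: int = 2

    def __post_init__(self) -> None:
        w = sum(s.weight for s in self.donor_sites)
        if abs(w - 1.0) > 1e-9:
            raise InvalidArgumentError(f"donor weights must sum to 1, got {w!r}")
        seen = set()
        for s in self.acceptor_sites:
            key = (s.chain_id, s.residue_number)
            if key in seen:
                raise InvalidArgumentError(
                    f"duplicate acceptor site chain {s.chain_id} residue {s.residue_number}"
                )
            seen.add(key)

    @property
    def donor_weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.donor_sites])

    def with_donor_weights(self, weights: Sequence[float]) -> "LabelingScheme":
        weights = np.asarray(weights, dtype=float)
        if weights.size != len(self.donor_sites):
            raise InvalidArgumentError("weight vector length does not match donor sites")
        donors = tuple(
            LabelSite(s.protein, s.chain_id, s.residue_number, s.role, float(w))
            for s, w in zip(self.donor_sites, weights)
        )
        return LabelingScheme(donors, self.acceptor_sites, self.donors_per_dimer, self.acceptors_per_dimer)

    def acceptor_positions(self) -> tuple:
        """Distinct acceptor residue numbers, ascending."""
        return tuple(sorted({s.residue_number for s in self.acceptor_sites}))


def default_scheme(
    acceptor_positions: Iterable[int] = AGP1_LABEL_POSITIONS,
    donor_positions: Iterable[int] = AGP2_LABEL_POSITIONS,
    chain_map: Mapping[str, Sequence[str]] = DEFAULT_CHAIN_MAP,
) -> LabelingScheme:
    """The experiment's labeling scheme with uniform donor occupancies."""
    donor_positions = tuple(donor_positions)
    donor_chains = tuple(chain_map["agp2"])
    n = len(donor_positions) * len(donor_chains)
    donors = tuple(
        LabelSite("agp2", ch, pos, "donor", 1.0 / n)
        for ch in donor_chains
        for pos in donor_positions
    )
    acceptors = tuple(
        LabelSite("agp1", ch, pos, "acceptor")
        for pos in acceptor_positions
        for ch in chain_map["agp1"]
    )
    return LabelingScheme(donors, acceptors)


def scheme_from_yaml(path) -> LabelingScheme:
    """Load a labeling scheme from YAML.

    Layout::

        donors:    [{protein: agp2, chain: C, residue: 29, weight: 0.0714}, ...]
        acceptors: [{protein: agp1, chain: A, residue: 517}, ...]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    donors = tuple(
        LabelSite(d["protein"], str(d["chain"]), int(d["residue"]), "donor", float(d.get("weight", 1.0)))
        for d in raw["donors"]
    )
    acceptors = tuple(
        LabelSite(a["protein"], str(a["chain"]), int(a["residue"]), "acceptor")
        for a in raw["acceptors"]
    )
    return LabelingScheme(
        donors,
        acceptors,
        donors_per_dimer=int(raw.get("donors_per_dimer", 1)),
        acceptors_per_dimer=int(raw.get("acceptors_per_dimer", 2)),
    )


@dataclass
class StructureModel:
    """Flat atomic-coordinate table of one candidate pose.

    ``atoms`` has columns chain_id, residue_number, residue_name, atom_name,
    x, y, z (Å).  No duplicate (chain, residue, atom_name) triples.
    """

    model_id: str
    atoms: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"chain_id", "residue_number", "residue_name", "atom_name", "x", "y", "z"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise InvalidArgumentError(f"atoms table missing columns {sorted(missing)}")
        dup = self.atoms.duplicated(["chain_id", "residue_number", "atom_name"])
        if dup.any():
            row = self.atoms[dup].iloc[0]
            raise FormatError(
                f"{self.model_id}: duplicate atom {row.atom_name} in chain "
                f"{row.chain_id} residue {int(row.residue_number)}"
            )
        if not np.isfinite(self.atoms[["x", "y", "z"]].to_numpy()).all():
            raise InvalidArgumentError(f"{self.model_id}: non-finite coordinates")

    @property
    def chain_ids(self) -> tuple:
        return tuple(pd.unique(self.atoms["chain_id"]))

    def coordinates(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray, chains=None) -> "StructureModel":
        """Apply a rigid transform (optionally only to the given chains)."""
        atoms = self.atoms.copy()
        mask = (
            atoms["chain_id"].isin(chains).to_numpy()
            if chains is not None
            else np.ones(len(atoms), dtype=bool)
        )
        xyz = atoms.loc[mask, ["x", "y", "z"]].to_numpy(dtype=float)
        atoms.loc[mask, ["x", "y", "z"]] = xyz @ np.asarray(rotation).T + np.asarray(translation)
        return StructureModel(self.model_id, atoms, self.provenance)


@dataclass(frozen=True)
class DistanceMatrix:
    """Acceptor-site x donor-site Euclidean distance matrix in Å."""

    rows: tuple  # acceptor site ids
    cols: tuple  # donor site ids
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "distances", d)
        if d.shape != (len(self.rows), len(self.cols)):
            raise InvalidArgumentError("distance matrix shape does not match site lists")
        if np.any(d < 0):
            raise InvalidArgumentError("distances must be nonnegative")


def read_structure(path, model_id: str | None = None) -> StructureModel:
    """Read ATOM records of a PDB v3.3 coordinate file.

    Chains and residue numbering are preserved; insertion codes are rejected;
    alternate locations collapse to the highest-occupancy conformer (ties
    broken by altloc letter order).  Fewer than two chains logs a warning.
    """
    path = Path(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise FormatError(f"{path}: unparseable PDB record ({exc})") from exc

    records = []
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.get_id()
            if hetflag.strip():
                continue  # HETATM records are not label-bearing residues
            if icode.strip():
                raise FormatError(
                    f"{path}: insertion code {icode!r} at chain {chain.id} residue "
                    f"{resseq} not supported"
                )
            for atom in residue:  # DisorderedAtom wrappers included
                if atom.is_disordered():
                    atom = max(
                        atom.disordered_get_list(),
                        key=lambda a: (a.get_occupancy() or 0.0, -ord(a.get_altloc() or " ")),
                    )
                x, y, z = atom.get_coord()
                records.append(
                    (chain.id, resseq, residue.get_resname(), atom.get_name(),
                     float(x), float(y), float(z))
                )
    atoms = pd.DataFrame(
        records,
        columns=["chain_id", "residue_number", "residue_name", "atom_name", "x", "y", "z"],
    )
    result = StructureModel(model_id or path.stem, atoms, provenance=str(path))
    if len(result.chain_ids) < 2:
        logger.warning("%s: fewer than 2 chains (%s)", path, result.chain_ids)
    return result


def write_structure(path, model: StructureModel) -> None:
    """Write a StructureModel as a PDB coordinate file."""
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure(model.model_id)
    builder.init_model(0)
    current_chain = None
    current_res = None
    builder.init_seg("    ")
    for row in model.atoms.itertuples(index=False):
        if row.chain_id != current_chain:
            builder.init_chain(row.chain_id)
            current_chain = row.chain_id
            current_res = None
        if row.residue_number != current_res:
            builder.init_residue(row.residue_name, " ", int(row.residue_number), " ")
            current_res = row.residue_number
        element = row.atom_name.strip()[0]
        builder.init_atom(
            row.atom_name,
            np.array([row.x, row.y, row.z], dtype=float),
            0.0,
            1.0,
            " ",
            row.atom_name.rjust(2) if len(row.atom_name) < 4 else row.atom_name,
            element=element,
        )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def site_coordinate(
    model: StructureModel,
    site: LabelSite,
    numbering_offset: int = 0,
) -> np.ndarray:
    """Cβ position of a label site (Cα fallback for glycine/missing Cβ).

    ``numbering_offset`` is added to the site's construct residue number to
    match structures using database numbering (the Agp1 construct carries
    nine extra N-terminal residues relative to database entries).
    """
    resnum = site.residue_number + numbering_offset
    sel = model.atoms[
        (model.atoms["chain_id"] == site.chain_id)
        & (model.atoms["residue_number"] == resnum)
    ]
    if sel.empty:
        raise MissingSiteError([site])
    cb = sel[sel["atom_name"] == "CB"]
    if not cb.empty:
        return cb.iloc[0][["x", "y", "z"]].to_numpy(dtype=float)
    ca = sel[sel["atom_name"] == "CA"]
    if not ca.empty:
        logger.warning(
            "%s: no CB for chain %s residue %d (%s); using CA",
            model.model_id, site.chain_id, resnum, sel.iloc[0]["residue_name"],
        )
        return ca.iloc[0][["x", "y", "z"]].to_numpy(dtype=float)
    raise MissingSiteError([site])


def distance_matrix(
    model: StructureModel,
    scheme: LabelingScheme,
    numbering_offsets: Mapping[str, int] | None = None,
) -> DistanceMatrix:
    """Euclidean acceptor-site x donor-site distances for a pose.

    For the experimental scheme (2 acceptor sites per Agp1 position, 14 donor
    sites) each acceptor position yields a 2 x 14 block — the 28 distances
    entering the efficiency prediction.
    """
    offsets = dict(numbering_offsets or {})
    missing, acc_xyz, don_xyz = [], [], []
    for s in scheme.acceptor_sites:
        try:
            acc_xyz.append(site_coordinate(model, s, offsets.get(s.protein, 0)))
        except MissingSiteError as exc:
            missing.extend(exc.sites)
    for s in scheme.donor_sites:
        try:
            don_xyz.append(site_coordinate(model, s, offsets.get(s.protein, 0)))
        except MissingSiteError as exc:
            missing.extend(exc.sites)
    if missing:
        raise MissingSiteError(missing)
    acc = np.asarray(acc_xyz)
    don = np.asarray(don_xyz)
    dists = np.linalg.norm(acc[:, None, :] - don[None, :, :], axis=-1)
    return DistanceMatrix(
        rows=tuple(s.site_id for s in scheme.acceptor_sites),
        cols=tuple(s.site_id for s in scheme.donor_sites),
        distances=dists,
    )


def site_table(model: StructureModel, scheme: LabelingScheme,
               numbering_offsets: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Resolved label-site coordinates as a table (site id, chain, residue, xyz)."""
    offsets = dict(numbering_offsets or {})
    rows = []
    for s in (*scheme.acceptor_sites, *scheme.donor_sites):
        xyz = site_coordinate(model, s, offsets.get(s.protein, 0))
        rows.append(
            {"site_id": s.site_id, "protein": s.protein, "chain": s.chain_id,
             "residue": s.residue_number, "role": s.role,
             "x": xyz[0], "y": xyz[1], "z": xyz[2]}
        )
    return pd.DataFrame(rows)
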