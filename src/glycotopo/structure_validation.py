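"""Structural re-validation of topology-based site calls.

Positions a parsed coordinate model against a membrane slab (two planes
perpendicular to the membrane normal, OPM/PDBTM style), remaps database
numbering onto structure numbering (signal-peptide removal and constant
offsets), detects covalently attached glycans, calls side-chain orientation
relative to a TM bundle, and combines everything into per-site verdicts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile
from biotite.structure.io.pdbx import get_structure as _cif_get_structure
from biotite.structure.io.pdbx import set_structure as _cif_set_structure

from .io_annotations import GlycoSite
from .topology_mapping import LocationLabel, SiteLocation

__all__ = [
    "StructureModel",
    "MembraneSlab",
    "NumberingMap",
    "SlabClass",
    "Verdict",
    "Orientation",
    "GlycanLink",
    "StructureVerdict",
    "read_structure",
    "write_structure",
    "read_slab",
    "build_numbering_map",
    "map_position",
    "slab_classify",
    "detect_covalent_glycans",
    "side_chain_orientation",
    "filter_confident_model",
    "verify_site",
]

#: monosaccharide residue names recognized as glycan components
GLYCAN_RESNAMES = frozenset(
    {"NAG", "NDG", "BMA", "MAN", "GAL", "GLC", "FUC", "FUL", "SIA", "XYS", "GLA", "A2G"}
)

#: backbone atom names excluded from side-chain geometry
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: glycan acceptor atoms on the protein, by residue name
ACCEPTOR_ATOMS = {"ASN": "ND2", "SER": "OG", "THR": "OG1"}

DEFAULT_BOND_CUTOFF = 2.0  # Å; covalent C-N/C-O ~1.4-1.5 Å
DEFAULT_COS_THRESHOLD = 0.5  # 60 degree cone for orientation calls
DEFAULT_CONFIDENCE_THRESHOLD = 70.0  # strict: confidence must exceed this

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


class SlabClass(str, Enum):
    MEMBRANE = "M"
    OUTSIDE = "O"
    INSIDE = "I"


class Verdict(str, Enum):
    CONFIRMED_IN_MEMBRANE = "confirmed_in_membrane"
    OUTSIDE_MEMBRANE = "outside_membrane"
    INTERFACE_CONFIRMED = "interface_confirmed"
    RELOCATED_EXTRAMEMBRANE = "relocated_extramembrane"
    ON_TM_HELIX = "on_tm_helix"
    RESIDUE_MISMATCH = "residue_mismatch"
    GLYCAN_ABSENT = "glycan_absent"
    UNRESOLVED = "unresolved"


class Orientation(str, Enum):
    LIPID_FACING = "lipid_facing"
    INTERIOR_FACING = "interior_facing"
    AMBIGUOUS = "ambiguous"
    NOT_APPLICABLE = "n/a"


class StructureError(ValueError):
    """Raised for unparseable files or failed residue/atom lookups."""


@dataclass(frozen=True)
class MembraneSlab:
    """Membrane region between two planes perpendicular to ``normal``.

    A point x is in the membrane when ``lower <= dot(x, normal) <= upper``
    (boundaries inclusive); above ``upper`` is outside (O), below ``lower``
    is inside (I).
    """

    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    lower: float = -15.0
    upper: float = 15.0

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = float(np.linalg.norm(n))
        if norm == 0.0:
            raise ValueError("slab normal must be nonzero")
        object.__setattr__(self, "normal", tuple(n / norm))
        if not self.upper - self.lower > 0:
            raise ValueError(
                f"slab upper ({self.upper}) must exceed lower ({self.lower})"
            )

    @property
    def normal_vector(self) -> np.ndarray:
        return np.asarray(self.normal, dtype=float)

    def axial(self, coords: np.ndarray) -> np.ndarray:
        """Coordinate(s) along the membrane normal."""
        return np.asarray(coords, dtype=float) @ self.normal_vector

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MembraneSlab":
        """Slab that co-moves with a model under x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_normal = rotation @ self.normal_vector
        shift = float(translation @ new_normal)
        return MembraneSlab(tuple(new_normal), self.lower + shift, self.upper + shift)


@dataclass
class StructureModel:
    """A coordinate model: chains of residues of atoms, with optional
    per-residue confidence (pLDDT-style, read from B-factors)."""

    atoms: struc.AtomArray

    def __post_init__(self) -> None:
        if self.atoms.array_length() and not np.all(np.isfinite(self.atoms.coord)):
            raise StructureError("non-finite coordinates in model")

    def __len__(self) -> int:
        return self.atoms.array_length()

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.atoms.chain_id:
            seen.setdefault(str(c), None)
        return list(seen)

    def residue_mask(self, chain: str, res_id: int, ins_code: str = "") -> np.ndarray:
        a = self.atoms
        mask = (a.chain_id == chain) & (a.res_id == res_id)
        if "ins_code" in a.get_annotation_categories():
            mask &= a.ins_code == ins_code
        return mask

    def has_residue(self, chain: str, res_id: int) -> bool:
        return bool(self.residue_mask(chain, res_id).any())

    def residue_atoms(self, chain: str, res_id: int) -> struc.AtomArray:
        sel = self.atoms[self.residue_mask(chain, res_id)]
        if sel.array_length() == 0:
            raise StructureError(f"residue {chain}/{res_id} not in model")
        return sel

    def residue_name(self, chain: str, res_id: int) -> str:
        return str(self.residue_atoms(chain, res_id).res_name[0])

    def atom_coord(self, chain: str, res_id: int, atom_name: str) -> np.ndarray:
        sel = self.residue_atoms(chain, res_id)
        hit = sel[sel.atom_name == atom_name]
        if hit.array_length() == 0:
            raise StructureError(f"atom {atom_name} missing in {chain}/{res_id}")
        return np.array(hit.coord[0], dtype=float)

    def residue_confidence(self, chain: str, res_id: int) -> Optional[float]:
        sel = self.residue_atoms(chain, res_id)
        if "b_factor" not in sel.get_annotation_categories():
            return None
        return float(np.mean(sel.b_factor))

    def chain_for_residue(self, res_id: int, preferred: Optional[str] = None) -> Optional[str]:
        """First chain containing the residue number (or ``preferred`` if it does)."""
        if preferred is not None and self.has_residue(preferred, res_id):
            return preferred
        for chain in self.chain_ids:
            if self.has_residue(chain, res_id):
                return chain
        return None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        moved = self.atoms.copy()
        moved.coord = moved.coord @ np.asarray(rotation, dtype=float).T + np.asarray(
            translation, dtype=float
        )
        return StructureModel(moved)


def read_structure(path: str | Path, fmt: Optional[str] = None) -> StructureModel:
    """Read a PDB or mmCIF coordinate file into a :class:`StructureModel`.

    All ATOM and HETATM records are retained (glycan residues included) and
    insertion codes are preserved. ``fmt`` is inferred from the extension when
    not given. A zero-atom file yields an empty model with a warning.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"pdb": "PDB", "ent": "PDB", "cif": "mmCIF", "mmcif": "mmCIF"}.get(
            suffix.lstrip("."), None
        )
        if fmt is None:
            raise StructureError(f"cannot infer format from extension of {path}")
    extra = ["b_factor"]
    try:
        if fmt.upper() == "PDB":
            pdb_file = PDBFile.read(str(path))
            if pdb_file.get_model_count() == 0:
                atoms = struc.AtomArray(0)
            else:
                atoms = pdb_file.get_structure(model=1, extra_fields=extra)
        elif fmt.lower() in ("mmcif", "cif"):
            atoms = _cif_get_structure(CIFFile.read(str(path)), model=1, extra_fields=extra)
        else:
            raise StructureError(f"unknown structure format {fmt!r}")
    except StructureError:
        raise
    except Exception as exc:
        raise StructureError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if atoms.array_length() == 0:
        warnings.warn(f"{path}: no atoms parsed; empty model", stacklevel=2)
    return StructureModel(atoms)


def write_structure(model: StructureModel, path: str | Path, fmt: Optional[str] = None) -> None:
    """Write a model as PDB or mmCIF (inferred from the extension)."""
    path = Path(path)
    if fmt is None:
        fmt = "PDB" if path.suffix.lower() in (".pdb", ".ent") else "mmCIF"
    if fmt.upper() == "PDB":
        f = PDBFile()
        f.set_structure(model.atoms)
        f.write(str(path))
    else:
        f = CIFFile()
        _cif_set_structure(f, model.atoms)
        f.write(str(path))


def read_slab(path: str | Path) -> MembraneSlab:
    """Read a membrane-plane sidecar: YAML/JSON with normal, lower, upper."""
    import yaml

    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return MembraneSlab(
        normal=tuple(data.get("normal", (0.0, 0.0, 1.0))),
        lower=float(data["lower"]),
        upper=float(data["upper"]),
    )


# ---------------------------------------------------------------------------
# numbering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NumberingMap:
    """Maps database (full-sequence) positions to structure author numbers.

    Positions inside a removed signal peptide map to None; all later positions
    shift down by the peptide length, then by ``offset``. Explicit
    (sequence, structure) pairs override the arithmetic and must be injective.
    """

    signal_peptide: Optional[tuple[int, int]] = None
    offset: int = 0
    pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.signal_peptide is not None:
            lo, hi = self.signal_peptide
            if not 1 <= lo <= hi:
                raise ValueError(f"bad signal peptide range [{lo},{hi}]")
        targets = [t for _, t in self.pairs]
        if len(set(targets)) != len(targets):
            raise ValueError("explicit numbering pairs must be injective")

    def __call__(self, position: int) -> Optional[int]:
        return map_position(self, position)


def build_numbering_map(
    signal_peptide: Optional[tuple[int, int]] = None,
    offset: int = 0,
    pairs: Optional[Iterable[tuple[int, int]]] = None,
) -> NumberingMap:
    return NumberingMap(
        signal_peptide=tuple(signal_peptide) if signal_peptide else None,
        offset=offset,
        pairs=tuple(tuple(p) for p in pairs) if pairs else (),
    )


def map_position(num_map: NumberingMap, position: int) -> Optional[int]:
    """Structure author number for a 1-based sequence position, or None when
    the position falls inside the removed signal peptide."""
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    for seq_pos, struct_pos in num_map.pairs:
        if seq_pos == position:
            return struct_pos
    shift = num_map.offset
    if num_map.signal_peptide is not None:
        lo, hi = num_map.signal_peptide
        if lo <= position <= hi:
            return None
        if position > hi:
            shift -= hi - lo + 1
    return position + shift


# ---------------------------------------------------------------------------
# slab membership
# ---------------------------------------------------------------------------

def slab_classify(
    model: StructureModel,
    slab: MembraneSlab,
    chain: str,
    res_id: int,
    atom_policy: str = "CA",
) -> SlabClass:
    """Locate a residue relative to the membrane slab.

    ``atom_policy="CA"`` (default) uses the C-alpha position; ``"any"`` labels
    the residue M when any of its atoms lies in (or its atoms straddle) the
    slab. Boundaries are inclusive.
    """
    if atom_policy == "CA":
        coords = model.atom_coord(chain, res_id, "CA")[np.newaxis, :]
    elif atom_policy == "any":
        coords = model.residue_atoms(chain, res_id).coord
    else:
        raise ValueError(f"unknown atom policy {atom_policy!r}")
    axial = slab.axial(coords)
    lo, hi = float(axial.min()), float(axial.max())
    if lo <= slab.upper and hi >= slab.lower:
        return SlabClass.MEMBRANE
    return SlabClass.OUTSIDE if lo > slab.upper else SlabClass.INSIDE


# ---------------------------------------------------------------------------
# covalent glycans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlycanLink:
    """A detected covalent glycan attachment."""

    glycan_chain: str
    glycan_res_id: int
    glycan_res_name: str
    protein_chain: str
    protein_res_id: int
    protein_res_name: str
    glycan_atom: str
    protein_atom: str
    distance: float


def detect_covalent_glycans(
    model: StructureModel, bond_cutoff: float = DEFAULT_BOND_CUTOFF
) -> list[GlycanLink]:
    """Report glycan residues covalently attached to the protein.

    A link is called when a glycan anomeric carbon (C1) lies within
    ``bond_cutoff`` of an Asn ND2 (N-linked) or a Ser OG / Thr OG1 (O-linked).
    Each glycan residue is linked to at most its nearest acceptor.
    """
    a = model.atoms
    if a.array_length() == 0:
        return []
    glycan_mask = np.isin(a.res_name, list(GLYCAN_RESNAMES)) & (a.atom_name == "C1")
    acceptor_mask = np.zeros(a.array_length(), dtype=bool)
    for res_name, atom_name in ACCEPTOR_ATOMS.items():
        acceptor_mask |= (a.res_name == res_name) & (a.atom_name == atom_name)
    if not glycan_mask.any() or not acceptor_mask.any():
        return []

    glycan_idx = np.flatnonzero(glycan_mask)
    acceptor_idx = np.flatnonzero(acceptor_mask)
    diffs = a.coord[glycan_idx][:, None, :] - a.coord[acceptor_idx][None, :, :]
    dists = np.sqrt((diffs**2).sum(axis=2))

    links: list[GlycanLink] = []
    for i, gi in enumerate(glycan_idx):
        j = int(np.argmin(dists[i]))
        d = float(dists[i, j])
        if d > bond_cutoff:
            continue
        ai = acceptor_idx[j]
        links.append(
            GlycanLink(
                glycan_chain=str(a.chain_id[gi]),
                glycan_res_id=int(a.res_id[gi]),
                glycan_res_name=str(a.res_name[gi]),
                protein_chain=str(a.chain_id[ai]),
                protein_res_id=int(a.res_id[ai]),
                protein_res_name=str(a.res_name[ai]),
                glycan_atom="C1",
                protein_atom=str(a.atom_name[ai]),
                distance=d,
            )
        )
    links.sort(key=lambda l: (l.glycan_chain, l.glycan_res_id))
    return links


# ---------------------------------------------------------------------------
# side-chain orientation
# ---------------------------------------------------------------------------

def _bundle_axis_point(model: StructureModel, tm_segments: Sequence[tuple[str, int, int]]) -> np.ndarray:
    """Centroid of all CA atoms in the given TM segments (the bundle axis is
    the line through this point along the slab normal)."""
    coords = []
    a = model.atoms
    for chain, start, end in tm_segments:
        mask = (
            (a.chain_id == chain)
            & (a.res_id >= start)
            & (a.res_id <= end)
            & (a.atom_name == "CA")
        )
        coords.append(a.coord[mask])
    stacked = np.concatenate(coords, axis=0) if coords else np.empty((0, 3))
    if stacked.shape[0] == 0:
        raise StructureError("no CA atoms found in the given TM segments")
    return stacked.mean(axis=0)


def _in_plane(vec: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return vec - (vec @ normal) * normal


def side_chain_orientation(
    model: StructureModel,
    slab: MembraneSlab,
    tm_segments: Sequence[tuple[str, int, int]],
    chain: str,
    res_id: int,
    cos_threshold: float = DEFAULT_COS_THRESHOLD,
) -> Orientation:
    """Call whether a residue's side chain points away from the TM bundle
    (lipid_facing) or into it (interior_facing / pore-facing for barrels).

    The bundle axis runs along the slab normal through the centroid of all
    TM-segment CA atoms; the call compares the in-plane side-chain direction
    (side-chain centroid minus CA) with the in-plane radial direction at the
    residue's CA. |cosine| below ``cos_threshold`` is ambiguous.
    """
    if len(tm_segments) < 2:
        raise ValueError("need >= 2 TM segments to define a bundle interior")
    res = model.residue_atoms(chain, res_id)
    ca_sel = res[res.atom_name == "CA"]
    if ca_sel.array_length() == 0:
        raise StructureError(f"residue {chain}/{res_id} has no CA atom")
    ca = np.array(ca_sel.coord[0], dtype=float)
    side = res[~np.isin(res.atom_name, list(BACKBONE_ATOMS)) & ~np.char.startswith(res.atom_name.astype(str), "H")]
    if side.array_length() == 0:
        warnings.warn(
            f"residue {chain}/{res_id} ({res.res_name[0]}) has no side-chain atoms; "
            "orientation ambiguous",
            stacklevel=2,
        )
        return Orientation.AMBIGUOUS

    normal = slab.normal_vector
    axis_point = _bundle_axis_point(model, tm_segments)
    radial = _in_plane(ca - axis_point, normal)
    sc_vec = _in_plane(side.coord.mean(axis=0) - ca, normal)
    r_norm, s_norm = np.linalg.norm(radial), np.linalg.norm(sc_vec)
    if r_norm < 1e-9 or s_norm < 1e-9:
        return Orientation.AMBIGUOUS
    cosine = float(radial @ sc_vec / (r_norm * s_norm))
    if cosine > cos_threshold:
        return Orientation.LIPID_FACING
    if cosine < -cos_threshold:
        return Orientation.INTERIOR_FACING
    return Orientation.AMBIGUOUS


# ---------------------------------------------------------------------------
# model confidence
# ---------------------------------------------------------------------------

def filter_confident_model(
    model: StructureModel,
    region: tuple[str, int, int],
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> bool:
    """True iff every residue in ``region`` (chain, start, end) has per-residue
    confidence strictly greater than ``threshold``."""
    chain, start, end = region
    a = model.atoms
    mask = (a.chain_id == chain) & (a.res_id >= start) & (a.res_id <= end)
    if not mask.any():
        raise StructureError(f"region {chain}:{start}-{end} not present in model")
    if "b_factor" not in a.get_annotation_categories():
        raise StructureError("model carries no per-residue confidence values")
    for res_id in range(start, end + 1):
        conf = model.residue_confidence(chain, res_id)
        if conf is None or not conf > threshold:
            return False
    return True


# ---------------------------------------------------------------------------
# per-site verdicts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureVerdict:
    """Structure-level outcome for one site."""

    site: GlycoSite
    verdict: Verdict
    glycan_found: bool = False
    orientation: Orientation = Orientation.NOT_APPLICABLE
    slab_class: Optional[SlabClass] = None
    mapped_position: Optional[int] = None
    chain: Optional[str] = None

    def __post_init__(self) -> None:
        if self.verdict is Verdict.RESIDUE_MISMATCH and self.glycan_found:
            raise ValueError("residue_mismatch implies glycan_found = False")


def verify_site(
    site: GlycoSite,
    location: SiteLocation,
    model: StructureModel,
    slab: MembraneSlab,
    num_map: Optional[NumberingMap] = None,
    *,
    chain: Optional[str] = None,
    tm_segments: Optional[Sequence[tuple[str, int, int]]] = None,
    bond_cutoff: float = DEFAULT_BOND_CUTOFF,
    require_glycan: bool = False,
    atom_policy: str = "CA",
) -> StructureVerdict:
    """Re-validate one annotation-level call against coordinates.

    The expected location (from ``location.label``) is compared with the
    residue's membrane-slab class at its mapped structure position; covalent
    glycan detection fills ``glycan_found``. With ``require_glycan`` the
    absence of an attached glycan dominates the verdict (annotation audit
    mode). Missing mapped residues yield ``unresolved``.
    """
    num_map = num_map or NumberingMap()
    mapped = map_position(num_map, site.position)
    if mapped is None:
        return StructureVerdict(site, Verdict.UNRESOLVED)
    use_chain = model.chain_for_residue(mapped, preferred=chain)
    if use_chain is None:
        return StructureVerdict(site, Verdict.UNRESOLVED, mapped_position=mapped)

    res_name = model.residue_name(use_chain, mapped)
    one_letter = THREE_TO_ONE.get(res_name, "X")
    if one_letter != site.residue:
        return StructureVerdict(
            site,
            Verdict.RESIDUE_MISMATCH,
            glycan_found=False,
            mapped_position=mapped,
            chain=use_chain,
        )

    links = detect_covalent_glycans(model, bond_cutoff)
    glycan_found = any(
        l.protein_chain == use_chain and l.protein_res_id == mapped for l in links
    )

    sclass = slab_classify(model, slab, use_chain, mapped, atom_policy)

    orientation = Orientation.NOT_APPLICABLE
    if sclass is SlabClass.MEMBRANE and tm_segments and len(tm_segments) >= 2:
        try:
            orientation = side_chain_orientation(model, slab, tm_segments, use_chain, mapped)
        except (StructureError, ValueError):
            orientation = Orientation.AMBIGUOUS

    if require_glycan and not glycan_found:
        verdict = Verdict.GLYCAN_ABSENT
    elif location.label is LocationLabel.IN_TM:
        verdict = (
            Verdict.CONFIRMED_IN_MEMBRANE
            if sclass is SlabClass.MEMBRANE
            else Verdict.RELOCATED_EXTRAMEMBRANE
        )
    elif location.label is LocationLabel.INTERFACE:
        verdict = (
            Verdict.ON_TM_HELIX
            if sclass is SlabClass.MEMBRANE
            else Verdict.INTERFACE_CONFIRMED
        )
    else:  # extramembrane expectation or annotation mismatch: report geometry
        verdict = (
            Verdict.ON_TM_HELIX if sclass is SlabClass.MEMBRANE else Verdict.OUTSIDE_MEMBRANE
        )

    return StructureVerdict(
        site,
        verdict,
        glycan_found=glycan_found,
        orientation=orientation,
        slab_class=sclass,
        mapped_position=mapped,
        chain=use_chain,
    )
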