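"""Seeded synthetic fixtures with known ground truth for every pipeline stage.

Two families of fixtures are generated: annotation sets (site + topology
tables with planted location labels) and idealized TM helix bundles crossing
a membrane slab, with planted covalent glycans, side-chain orientations and
author-numbering offsets. All outputs are pure functions of (parameters,
seed).

Ideal alpha-helix constants: 1.5 A rise per residue along the axis, 100
degrees rotation per residue, 2.3 A CA radius (textbook geometry). Glycan
pseudo-residues carry only an anomeric carbon (C1) and a ring-centroid marker
-- enough for covalent-link detection without conformer chemistry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import biotite.structure as struc

from .io_annotations import (
    GlycanClass,
    GlycoSite,
    PredictionProfile,
    SegmentClass,
    SiteStatus,
    TopoSegment,
    TopologyAnnotation,
    write_prediction_profiles,
    write_site_table,
    write_topology_table,
)
from .structure_validation import (
    ACCEPTOR_ATOMS,
    MembraneSlab,
    StructureModel,
    write_structure,
)

__all__ = [
    "ALPHA_RISE",
    "ALPHA_TWIST_DEG",
    "ALPHA_CA_RADIUS",
    "FixtureTruth",
    "generate_annotation_set",
    "generate_helix",
    "generate_bundle",
    "generate_profiles",
    "write_annotation_fixture",
    "write_bundle_fixture",
]

ALPHA_RISE = 1.5
ALPHA_TWIST_DEG = 100.0
ALPHA_CA_RADIUS = 2.3
SIDECHAIN_LENGTH = 1.5
GLYCAN_BOND_LENGTH = 1.45


@dataclass
class FixtureTruth:
    """Planted ground truth; fully determines expected downstream outputs.

    Keys are strings: site labels use ``"ACCESSION:position"``, structural
    entries use ``"chain:res_id"`` in author numbering.
    """

    seed: int
    site_labels: dict[str, str] = field(default_factory=dict)
    slab_classes: dict[str, str] = field(default_factory=dict)
    glycan_links: list[dict] = field(default_factory=list)
    orientations: dict[str, str] = field(default_factory=dict)
    tm_segments: list[list] = field(default_factory=list)
    numbering_offset: int = 0
    interface_window: int = 0
    disagreement_positions: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureTruth":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# annotation fixtures
# ---------------------------------------------------------------------------

def generate_annotation_set(
    n_proteins: int,
    tm_segments_per_protein: int = 2,
    sites_per_protein: int = 3,
    w: int = 3,
    seed: int = 0,
) -> tuple[list[GlycoSite], dict[str, TopologyAnnotation], FixtureTruth]:
    """Generate site and topology tables with planted location labels.

    Each protein gets TM segments separated by gaps wide enough to plant
    interface sites (distance 1..w from a segment) and extramembrane sites
    (distance > w from every segment); planted classes cycle in_tm /
    interface / extramembrane so each class is represented.
    """
    if n_proteins < 0:
        raise ValueError("n_proteins must be >= 0")
    if n_proteins and (tm_segments_per_protein < 1 or sites_per_protein < 0 or w < 0):
        raise ValueError("parameters must be positive")
    seg_len = 21
    gap = seg_len + 2 * w + 10
    rng = np.random.default_rng(seed)
    sites: list[GlycoSite] = []
    topologies: dict[str, TopologyAnnotation] = {}
    truth = FixtureTruth(seed=seed, interface_window=w)

    classes = ["in_tm", "interface", "extramembrane"]
    if w == 0:
        classes = ["in_tm", "extramembrane"]

    for p in range(n_proteins):
        accession = f"SYN{p:04d}"
        segments = []
        cursor = gap
        for _ in range(tm_segments_per_protein):
            segments.append(
                TopoSegment(cursor, cursor + seg_len - 1, SegmentClass.TM_HELIX, "planted")
            )
            cursor += seg_len + gap
        seq_len = cursor + gap
        if sites_per_protein > seq_len:
            raise ValueError(
                f"cannot plant {sites_per_protein} sites in {seq_len} residues"
            )
        topologies[accession] = TopologyAnnotation(accession, tuple(segments), seq_len)

        used: set[int] = set()
        for s in range(sites_per_protein):
            label = classes[s % len(classes)]
            for _attempt in range(200):
                seg = segments[int(rng.integers(len(segments)))]
                if label == "in_tm":
                    pos = int(rng.integers(seg.start, seg.end + 1))
                elif label == "interface":
                    d = int(rng.integers(1, w + 1))
                    pos = seg.start - d if rng.random() < 0.5 else seg.end + d
                else:  # extramembrane: beyond w of every segment
                    d = int(rng.integers(w + 1, w + 8))
                    pos = seg.start - d if rng.random() < 0.5 else seg.end + d
                    if any(other.distance_to(pos) <= w for other in segments):
                        continue
                if pos < 1 or pos > seq_len or pos in used:
                    continue
                break
            else:  # pragma: no cover - layout guarantees success
                raise ValueError("failed to plant site; parameters infeasible")
            used.add(pos)
            residue = "S" if rng.random() < 0.5 else "T"
            sites.append(
                GlycoSite(
                    accession=accession,
                    position=pos,
                    residue=residue,
                    glycan_class=GlycanClass.O_GLCNAC,
                    status=SiteStatus.REPORTED,
                    evidence=(f"SYNSET{seed}",),
                    protein_name=f"synthetic protein {p}",
                )
            )
            truth.site_labels[f"{accession}:{pos}"] = label
    return sites, topologies, truth


def write_annotation_fixture(
    out_dir: str | Path,
    n_proteins: int,
    tm_segments_per_protein: int = 2,
    sites_per_protein: int = 3,
    w: int = 3,
    seed: int = 0,
) -> FixtureTruth:
    """Generate an annotation set and write sites.tsv / topology.tsv / truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sites, topologies, truth = generate_annotation_set(
        n_proteins, tm_segments_per_protein, sites_per_protein, w, seed
    )
    write_site_table(sites, out_dir / "sites.tsv")
    write_topology_table(topologies, out_dir / "topology.tsv")
    truth.to_json(out_dir / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# coordinate fixtures
# ---------------------------------------------------------------------------

def generate_helix(
    n_res: int,
    start_res: int = 1,
    z_center: float = 0.0,
    phase_deg: float = 0.0,
    chain_id: str = "A",
    direction: int = 1,
    center_xy: tuple[float, float] = (0.0, 0.0),
    res_names: Optional[Sequence[str]] = None,
) -> struc.AtomArray:
    """Ideal alpha-helix along the z axis: one CA plus one radially outward
    side-chain pseudo-atom (CB) per residue, centered axially on ``z_center``.

    ``direction=-1`` runs the chain antiparallel (z decreasing with residue
    number). CA axial extent is (n_res - 1) * 1.5 A.
    """
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    if res_names is not None and len(res_names) != n_res:
        raise ValueError("res_names must have one entry per residue")
    cx, cy = center_xy
    atoms = []
    for i in range(n_res):
        theta = np.deg2rad(phase_deg + i * ALPHA_TWIST_DEG)
        z = z_center + (i - (n_res - 1) / 2.0) * ALPHA_RISE * direction
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        ca = np.array([cx, cy, z]) + ALPHA_CA_RADIUS * radial
        cb = ca + SIDECHAIN_LENGTH * radial
        name = res_names[i] if res_names is not None else "LEU"
        res_id = start_res + i
        atoms.append(
            struc.Atom(ca, chain_id=chain_id, res_id=res_id, res_name=name,
                       atom_name="CA", element="C", hetero=False)
        )
        atoms.append(
            struc.Atom(cb, chain_id=chain_id, res_id=res_id, res_name=name,
                       atom_name="CB", element="C", hetero=False)
        )
    arr = struc.array(atoms)
    arr.set_annotation("b_factor", np.full(arr.array_length(), 90.0))
    return arr


def generate_bundle(
    n_helices: int = 4,
    n_res: int = 30,
    bundle_radius: float = 8.0,
    slab: Optional[MembraneSlab] = None,
    glycan_plants: Optional[Mapping[int, str]] = None,
    orientation_plants: Optional[Mapping[int, str]] = None,
    numbering_offset: int = 0,
    seed: int = 0,
) -> tuple[StructureModel, MembraneSlab, FixtureTruth]:
    """Build a TM helix bundle (single chain A) with planted ground truth.

    Helices sit on a circle of ``bundle_radius``, alternating direction, axes
    parallel to the slab normal (z). ``glycan_plants`` maps a *sequence*
    position to an acceptor residue name (ASN / SER / THR); a NAG
    pseudo-residue is bonded there at 1.45 A. ``orientation_plants`` maps a
    sequence position to ``lipid_facing`` (side chain radially outward from
    the bundle axis) or ``interior_facing`` (flipped inward).

    Sequence positions run ``numbering_offset + 1 .. numbering_offset + n``;
    author numbers in the file run ``1 .. n`` (signal-peptide-removal style).
    """
    if n_helices < 2:
        raise ValueError("need >= 2 helices for orientation tests")
    slab = slab or MembraneSlab()
    glycan_plants = dict(glycan_plants or {})
    orientation_plants = dict(orientation_plants or {})
    rng = np.random.default_rng(seed)
    truth = FixtureTruth(seed=seed, numbering_offset=numbering_offset)

    n_total = n_helices * n_res
    seq_lo, seq_hi = numbering_offset + 1, numbering_offset + n_total
    for plants, kind in ((glycan_plants, "glycan"), (orientation_plants, "orientation")):
        for pos in plants:
            if not seq_lo <= pos <= seq_hi:
                raise ValueError(
                    f"{kind} plant at sequence position {pos} outside "
                    f"[{seq_lo},{seq_hi}]"
                )
    for pos, name in glycan_plants.items():
        if name not in ACCEPTOR_ATOMS:
            raise ValueError(f"glycan plant residue must be ASN/SER/THR, got {name}")

    helices = []
    for k in range(n_helices):
        phi = 2.0 * np.pi * k / n_helices
        center = (bundle_radius * np.cos(phi), bundle_radius * np.sin(phi))
        helices.append(
            generate_helix(
                n_res,
                start_res=1 + k * n_res,
                z_center=0.0,
                phase_deg=float(rng.uniform(0.0, 360.0)),
                chain_id="A",
                direction=1 if k % 2 == 0 else -1,
                center_xy=center,
            )
        )
        truth.tm_segments.append(["A", 1 + k * n_res, (k + 1) * n_res])
    arr = helices[0]
    for h in helices[1:]:
        arr = arr + h

    ca_mask = arr.atom_name == "CA"
    axis_point = arr.coord[ca_mask].mean(axis=0)
    normal = slab.normal_vector  # (0,0,1) at generation time

    def _author(pos: int) -> int:
        return pos - numbering_offset

    def _residue_indices(res_id: int) -> np.ndarray:
        return np.flatnonzero(arr.res_id == res_id)

    # orientation plants: re-point the side-chain pseudo-atom relative to the
    # bundle axis; record truth
    for pos, wanted in orientation_plants.items():
        res_id = _author(pos)
        idx = _residue_indices(res_id)
        ca_idx = idx[arr.atom_name[idx] == "CA"][0]
        cb_idx = idx[arr.atom_name[idx] == "CB"][0]
        ca = arr.coord[ca_idx]
        radial = ca - axis_point
        radial[2] = 0.0
        radial /= np.linalg.norm(radial)
        sign = {"lipid_facing": 1.0, "interior_facing": -1.0}[wanted]
        arr.coord[cb_idx] = ca + sign * SIDECHAIN_LENGTH * radial
        truth.orientations[f"A:{res_id}"] = wanted

    # glycan plants: rename residue + side-chain atom to a real acceptor and
    # bond a NAG pseudo-residue at 1.45 A outward
    glycan_atoms = []
    for i, (pos, res_name) in enumerate(sorted(glycan_plants.items())):
        res_id = _author(pos)
        idx = _residue_indices(res_id)
        arr.res_name[idx] = res_name
        cb_idx = idx[arr.atom_name[idx] == "CB"][0]
        ca_idx = idx[arr.atom_name[idx] == "CA"][0]
        arr.atom_name[cb_idx] = ACCEPTOR_ATOMS[res_name]
        acceptor = arr.coord[cb_idx]
        outward = acceptor - arr.coord[ca_idx]
        outward /= np.linalg.norm(outward)
        c1 = acceptor + GLYCAN_BOND_LENGTH * outward
        marker = c1 + SIDECHAIN_LENGTH * outward
        nag_id = 900 + i
        glycan_atoms.append(
            struc.Atom(c1, chain_id="X", res_id=nag_id, res_name="NAG",
                       atom_name="C1", element="C", hetero=True)
        )
        glycan_atoms.append(
            struc.Atom(marker, chain_id="X", res_id=nag_id, res_name="NAG",
                       atom_name="C4", element="C", hetero=True)
        )
        truth.glycan_links.append(
            {
                "glycan_chain": "X",
                "glycan_res_id": nag_id,
                "protein_chain": "A",
                "protein_res_id": res_id,
                "protein_atom": ACCEPTOR_ATOMS[res_name],
                "distance": GLYCAN_BOND_LENGTH,
            }
        )

    if glycan_atoms:
        gly = struc.array(glycan_atoms)
        gly.set_annotation("b_factor", np.full(gly.array_length(), 0.0))
        arr = arr + gly

    # slab-class truth from construction-time axial coordinates
    for res_id in range(1, n_total + 1):
        idx = _residue_indices(res_id)
        ca_idx = idx[arr.atom_name[idx] == "CA"][0]
        z = float(arr.coord[ca_idx] @ normal)
        if slab.lower <= z <= slab.upper:
            cls = "M"
        elif z > slab.upper:
            cls = "O"
        else:
            cls = "I"
        truth.slab_classes[f"A:{res_id}"] = cls

    return StructureModel(arr), slab, truth


def write_bundle_fixture(
    out_dir: str | Path,
    fmt: str = "pdb",
    **kwargs,
) -> FixtureTruth:
    """Generate a bundle and write bundle.<fmt>, slab.yaml and truth.json."""
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, slab, truth = generate_bundle(**kwargs)
    write_structure(model, out_dir / f"bundle.{fmt}")
    sidecar = {
        "normal": [float(x) for x in slab.normal],
        "lower": float(slab.lower),
        "upper": float(slab.upper),
    }
    (out_dir / "slab.yaml").write_text(
        yaml.safe_dump(sidecar, sort_keys=True), encoding="utf-8"
    )
    truth.to_json(out_dir / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# predictor-profile fixtures
# ---------------------------------------------------------------------------

def generate_profiles(
    topology: TopologyAnnotation,
    n_predictors: int = 8,
    disagree_positions: Iterable[int] = (),
    seed: int = 0,
) -> tuple[list[PredictionProfile], FixtureTruth]:
    """Profiles matching a reference annotation except at chosen positions,
    where a strict majority of predictors is flipped."""
    if topology.sequence_length is None:
        raise ValueError("topology needs sequence_length to build profiles")
    length = topology.sequence_length
    base = ["I"] * length
    for seg in topology.tm_segments:
        for pos in range(seg.start, seg.end + 1):
            base[pos - 1] = "M"
    profiles = []
    n_flip = n_predictors // 2 + 1
    disagree = sorted(set(disagree_positions))
    truth = FixtureTruth(seed=seed, disagreement_positions=list(disagree))
    for p in range(n_predictors):
        labels = base.copy()
        if p < n_flip:
            for pos in disagree:
                labels[pos - 1] = "I" if labels[pos - 1] == "M" else "M"
        profiles.append(PredictionProfile(f"predictor_{p}", "".join(labels)))
    return profiles, truth
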