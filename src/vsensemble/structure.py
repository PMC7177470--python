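"""Structural statistics for frame selection and MD interpretation.

Covers the geometry side of an ensemble-docking study on a homotetrameric
channel: Kabsch superposition and RMSD over named atom selections,
per-segment RMSD profiles along a trajectory, selection of the MD frames
whose binding site best matches reference crystal structures, solvent-
accessible surface area (Shrake-Rupley, 1.4 A probe by default), the
inter-monomeric contact surface

    sigma(t) = (S_monomer(t) + S_trimer(t) - S_tetramer(t)) / 2,

and pairwise electrostatic / Lennard-Jones interaction energies between
atom groups with a distance-dependent dielectric eps(r) = eps0 * r.

Coordinates are held in a plain :class:`CoordinateSet` (one model/frame of
a PDB file); multi-model PDB files are read as frame sequences via gemmi.
Residue numbering is taken as authored (hTRPM8 numbering, e.g. 745, 1004).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "CoordinateSet",
    "AtomSelection",
    "SasaSeries",
    "EnergyParams",
    "BINDING_SITE_RESIDUES",
    "SEGMENTS",
    "BACKBONE_ATOMS",
    "BONDI_RADII",
    "binding_site_backbone",
    "binding_site_heavy",
    "read_pdb",
    "write_pdb",
    "kabsch_superpose",
    "rmsd",
    "pose_rmsd",
    "rmsd_profile",
    "select_frames",
    "sasa",
    "contact_surface_series",
    "pairwise_interaction_energy",
    "COULOMB_CONSTANT",
]

#: S1-S4 sensor-domain binding-site residues (hTRPM8 numbering):
#: Y745, I746, L778, E782, Q785, N799, D802, F838, R841, H844, E1003,
#: Y1004, F1012.
BINDING_SITE_RESIDUES = frozenset(
    {745, 746, 778, 782, 785, 799, 802, 838, 841, 844, 1003, 1004, 1012}
)

#: Transmembrane sensor helices and the TRP box (residue ranges, inclusive).
SEGMENTS: dict[str, range] = {
    "S1": range(736, 758),
    "S2": range(769, 789),
    "S3": range(797, 817),
    "S4": range(824, 852),
    "TRP": range(992, 1009),
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Bondi van der Waals radii (A) by element symbol.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

COULOMB_CONSTANT = 332.0716  # kcal*A/(mol*e^2)


@dataclass
class CoordinateSet:
    """Labelled atoms of one model/frame: arrays of equal length N."""

    chain: np.ndarray
    resnum: np.ndarray
    resname: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    xyz: np.ndarray
    frame_id: str | None = None

    def __post_init__(self) -> None:
        n = len(self.chain)
        for name in ("resnum", "resname", "atom_name", "element"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} has wrong length")
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (n, 3):
            raise ValueError("xyz must have shape (N, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.chain)

    def atom_keys(self) -> list[tuple[str, int, str]]:
        return list(zip(self.chain, self.resnum.astype(int), self.atom_name))

    def subset(self, mask: np.ndarray) -> "CoordinateSet":
        return CoordinateSet(
            self.chain[mask],
            self.resnum[mask],
            self.resname[mask],
            self.atom_name[mask],
            self.element[mask],
            self.xyz[mask],
            self.frame_id,
        )

    def transformed(self, rotation: Rotation, translation: np.ndarray) -> "CoordinateSet":
        return CoordinateSet(
            self.chain.copy(),
            self.resnum.copy(),
            self.resname.copy(),
            self.atom_name.copy(),
            self.element.copy(),
            rotation.apply(self.xyz) + translation,
            self.frame_id,
        )


@dataclass(frozen=True)
class AtomSelection:
    """Predicate over atoms: residues, atom names, chains, heavy-only."""

    residues: frozenset[int] | None = None
    atom_names: frozenset[str] | None = None
    chains: frozenset[str] | None = None
    heavy_only: bool = False
    name: str = ""

    def mask(self, cs: CoordinateSet) -> np.ndarray:
        m = np.ones(len(cs), dtype=bool)
        if self.residues is not None:
            m &= np.isin(cs.resnum.astype(int), list(self.residues))
        if self.atom_names is not None:
            m &= np.isin(cs.atom_name, list(self.atom_names))
        if self.chains is not None:
            m &= np.isin(cs.chain, list(self.chains))
        if self.heavy_only:
            m &= cs.element != "H"
        return m


def binding_site_backbone(chains: Sequence[str] | None = None) -> AtomSelection:
    """Backbone (N, CA, C, O) atoms of the binding-site residues."""
    return AtomSelection(
        residues=BINDING_SITE_RESIDUES,
        atom_names=BACKBONE_ATOMS,
        chains=frozenset(chains) if chains else None,
        name="binding_site_backbone",
    )


def binding_site_heavy(chains: Sequence[str] | None = None) -> AtomSelection:
    """All heavy atoms of the binding-site residues (side chains included)."""
    return AtomSelection(
        residues=BINDING_SITE_RESIDUES,
        chains=frozenset(chains) if chains else None,
        heavy_only=True,
        name="binding_site_heavy",
    )


def segment_selection(segment: str, chains: Sequence[str] | None = None) -> AtomSelection:
    """Backbone selection for one named segment (S1-S4, TRP)."""
    if segment not in SEGMENTS:
        raise KeyError(f"unknown segment {segment!r}; have {sorted(SEGMENTS)}")
    return AtomSelection(
        residues=frozenset(SEGMENTS[segment]),
        atom_names=BACKBONE_ATOMS,
        chains=frozenset(chains) if chains else None,
        name=segment,
    )


# -- PDB I/O (gemmi) -----------------------------------------------------


def read_pdb(path: str | Path) -> list[CoordinateSet]:
    """Read a (possibly multi-model) PDB file as a list of frames.

    Alternate locations beyond the first are skipped; hydrogens are kept.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    frames: list[CoordinateSet] = []
    for model in st:
        chains, resnums, resnames, names, elements, xyz = [], [], [], [], [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.altloc not in ("", "\x00", "A"):
                        continue
                    chains.append(chain.name)
                    resnums.append(residue.seqid.num)
                    resnames.append(residue.name)
                    names.append(atom.name)
                    elements.append(atom.element.name.upper())
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        model_id = getattr(model, "num", None)
        if model_id is None:
            model_id = getattr(model, "name", len(frames) + 1)
        frames.append(
            CoordinateSet(
                np.array(chains),
                np.array(resnums, dtype=int),
                np.array(resnames),
                np.array(names),
                np.array(elements),
                np.array(xyz, dtype=float),
                frame_id=str(model_id),
            )
        )
    if not frames:
        raise ValueError(f"no models found in {path}")
    return frames


def write_pdb(frames: CoordinateSet | Sequence[CoordinateSet], path: str | Path) -> None:
    """Write one or more frames as a (multi-model) PDB file."""
    import gemmi

    if isinstance(frames, CoordinateSet):
        frames = [frames]
    st = gemmi.Structure()
    st.name = Path(path).stem
    for i, cs in enumerate(frames, start=1):
        try:
            model = gemmi.Model(i)
        except TypeError:  # older gemmi wants a string name
            model = gemmi.Model(str(i))
        # gemmi's add_* methods copy their argument, so every container is
        # fully populated before being added to its parent
        for chain_name in dict.fromkeys(cs.chain):
            chain = gemmi.Chain(str(chain_name))
            sel = np.flatnonzero(cs.chain == chain_name)
            residues: list = []
            current_res = None
            for idx in sel:
                key = (int(cs.resnum[idx]), str(cs.resname[idx]))
                if key != current_res:
                    residue = gemmi.Residue()
                    residue.name = str(cs.resname[idx])
                    residue.seqid = gemmi.SeqId(int(cs.resnum[idx]), " ")
                    residues.append(residue)
                    current_res = key
                atom = gemmi.Atom()
                atom.name = str(cs.atom_name[idx])
                atom.element = gemmi.Element(str(cs.element[idx]).capitalize())
                atom.pos = gemmi.Position(*cs.xyz[idx])
                residues[-1].add_atom(atom)
            for residue in residues:
                chain.add_residue(residue)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# -- superposition and RMSD ----------------------------------------------


def _paired_coords(
    a: CoordinateSet,
    b: CoordinateSet,
    selection: AtomSelection,
    strict: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of atoms matched by (chain, resnum, atom_name)."""
    ma, mb = selection.mask(a), selection.mask(b)
    all_a, all_b = a.atom_keys(), b.atom_keys()
    keys_a = [all_a[i] for i in np.flatnonzero(ma)]
    keys_b = [all_b[i] for i in np.flatnonzero(mb)]
    map_a = dict(zip(keys_a, np.flatnonzero(ma)))
    map_b = dict(zip(keys_b, np.flatnonzero(mb)))
    common = [k for k in keys_a if k in map_b]
    if strict:
        unpaired = [k for k in keys_a if k not in map_b]
        unpaired += [k for k in keys_b if k not in map_a]
        if unpaired:
            raise ValueError(
                f"{len(unpaired)} unpaired fit atoms; first 10: {unpaired[:10]}"
            )
    if not common:
        raise ValueError("selection pairs no atoms between the two structures")
    pa = a.xyz[[map_a[k] for k in common]]
    pb = b.xyz[[map_b[k] for k in common]]
    return pa, pb


def kabsch_superpose(
    mobile: CoordinateSet,
    reference: CoordinateSet,
    fit_selection: AtomSelection | None = None,
) -> CoordinateSet:
    """Least-squares superpose ``mobile`` onto ``reference``.

    The optimal proper rotation (det = +1) is found on the atoms of
    ``fit_selection`` paired by (chain, residue, atom name); the transform
    is applied to all atoms of ``mobile``.
    """
    if fit_selection is None:
        fit_selection = AtomSelection(name="all")
    pm, pr = _paired_coords(mobile, reference, fit_selection, strict=True)
    if len(pm) < 3:
        raise ValueError("need at least 3 paired atoms for superposition")
    cm, cr = pm.mean(axis=0), pr.mean(axis=0)
    rot, _ = Rotation.align_vectors(pr - cr, pm - cm)
    translation = cr - rot.apply(cm)
    return mobile.transformed(rot, translation)


def rmsd(
    a: CoordinateSet,
    b: CoordinateSet,
    selection: AtomSelection | None = None,
    superpose: bool = False,
    fit_selection: AtomSelection | None = None,
) -> float:
    """RMSD (A) over paired atoms of ``selection``.

    With ``superpose``, ``a`` is first Kabsch-fitted to ``b`` on
    ``fit_selection`` (defaulting to ``selection`` itself).
    """
    if selection is None:
        selection = AtomSelection(name="all")
    if superpose:
        a = kabsch_superpose(a, b, fit_selection or selection)
    pa, pb = _paired_coords(a, b, selection)
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def rmsd_profile(
    frames: Sequence[CoordinateSet],
    reference: CoordinateSet,
    selections: Mapping[str, AtomSelection],
    superpose: bool = False,
    fit_selection: AtomSelection | None = None,
) -> pd.DataFrame:
    """Per-frame, per-selection RMSD table (frames as rows).

    Frames missing the selected atoms get NaN in that cell and are excluded
    from column means (``profile.mean(skipna=True)``).
    """
    rows = {}
    for i, frame in enumerate(frames):
        fid = frame.frame_id if frame.frame_id is not None else str(i)
        row = {}
        for name, sel in selections.items():
            try:
                row[name] = rmsd(frame, reference, sel, superpose, fit_selection)
            except ValueError:
                row[name] = np.nan
        rows[fid] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(selections))


def select_frames(
    frames: Sequence[CoordinateSet],
    references: Mapping[str, CoordinateSet],
    chains: Sequence[str],
    superpose: bool = True,
) -> pd.DataFrame:
    """Pick, per chain x reference x criterion, the frame of minimum RMSD.

    Criteria are the two binding-site views used for frame selection:
    ``backbone`` (N, CA, C, O of the binding-site residues) and ``heavy``
    (all heavy atoms of those residues).  Superposition fits on the
    binding-site backbone of the same chain.  Returns a tidy table with
    one row per (chain, reference, criterion).
    """
    if not chains:
        raise ValueError("no chains given")
    records = []
    for chain in chains:
        fit = binding_site_backbone([chain])
        criteria = {
            "backbone": binding_site_backbone([chain]),
            "heavy": binding_site_heavy([chain]),
        }
        for ref_name, ref in references.items():
            if not np.any(fit.mask(ref)) or not any(
                np.any(fit.mask(f)) for f in frames
            ):
                raise ValueError(f"chain {chain!r} not resolvable in inputs")
            for crit_name, crit in criteria.items():
                best_frame, best_val = None, np.inf
                for i, frame in enumerate(frames):
                    fid = frame.frame_id if frame.frame_id is not None else str(i)
                    try:
                        val = rmsd(
                            frame, ref, crit,
                            superpose=superpose, fit_selection=fit,
                        )
                    except ValueError:
                        continue
                    if val < best_val:
                        best_frame, best_val = fid, val
                records.append(
                    {
                        "chain": chain,
                        "reference": ref_name,
                        "criterion": crit_name,
                        "best_frame": best_frame,
                        "rmsd": best_val,
                    }
                )
    return pd.DataFrame.from_records(records)


def pose_rmsd(a: CoordinateSet, b: CoordinateSet) -> float:
    """Ligand-pose RMSD (A) in a shared frame: atoms paired by order.

    No superposition and no symmetry correction — the convention of
    indirect re-docking comparisons, where poses are already expressed in
    the receptor frame and symmetric binding modes are reported as large
    deviations rather than folded together.
    """
    if len(a) != len(b):
        raise ValueError(f"pose atom counts differ: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty pose")
    return float(np.sqrt(np.mean(np.sum((a.xyz - b.xyz) ** 2, axis=1))))


# -- surface areas -------------------------------------------------------


def _vdw_radii(cs: CoordinateSet, radii: Mapping[str, float] | None) -> np.ndarray:
    table = dict(BONDI_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    out = np.empty(len(cs))
    for i, el in enumerate(cs.element):
        r = table.get(str(el).upper())
        if r is None:
            raise KeyError(f"no van der Waals radius for element {el!r}; "
                           "pass an override in `radii`")
        out[i] = r
    return out


def sasa(
    structure: CoordinateSet,
    probe: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area (A^2).

    Each atom's van der Waals sphere (Bondi radii by default, overridable
    per element) is extended by the probe radius and sampled with
    ``n_points`` sphere points.  Returns (per-atom areas, total).
    """
    import biotite.structure as bst

    n = len(structure)
    arr = bst.AtomArray(n)
    arr.coord = structure.xyz.astype(np.float32)
    arr.chain_id = structure.chain.astype("U4")
    arr.res_id = structure.resnum.astype(int)
    arr.res_name = structure.resname.astype("U5")
    arr.atom_name = structure.atom_name.astype("U6")
    arr.element = np.char.upper(structure.element.astype("U2"))
    per_atom = bst.sasa(
        arr,
        probe_radius=float(probe),
        point_number=int(n_points),
        vdw_radii=_vdw_radii(structure, radii),
        ignore_ions=False,
    )
    per_atom = np.nan_to_num(per_atom, nan=0.0)
    return per_atom, float(per_atom.sum())


@dataclass
class SasaSeries:
    """Per-frame monomer/trimer/tetramer SASA and the derived contact
    surface sigma(t) = (S_monomer + S_trimer - S_tetramer) / 2."""

    frame_ids: list[str]
    s_monomer: np.ndarray
    s_trimer: np.ndarray
    s_tetramer: np.ndarray
    probe: float = 1.4

    @property
    def sigma(self) -> np.ndarray:
        return (self.s_monomer + self.s_trimer - self.s_tetramer) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_monomer": self.s_monomer,
                "s_trimer": self.s_trimer,
                "s_tetramer": self.s_tetramer,
                "sigma": self.sigma,
            },
            index=pd.Index(self.frame_ids, name="frame"),
        )


def contact_surface_series(
    frames: Sequence[CoordinateSet],
    reference_chain: str = "A",
    probe: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
) -> SasaSeries:
    """Buried interface between one chain and the rest, per frame.

    For each frame: SASA of the reference chain alone, of the remaining
    chains alone, and of the full assembly; sigma(t) is half the total
    buried area, which vanishes when the groups are out of contact.
    """
    ids, s_m, s_t, s_all = [], [], [], []
    for i, frame in enumerate(frames):
        in_ref = frame.chain == reference_chain
        if not np.any(in_ref):
            raise ValueError(
                f"reference chain {reference_chain!r} absent in frame "
                f"{frame.frame_id or i}"
            )
        if np.all(in_ref):
            raise ValueError("need at least 2 chains per frame")
        ids.append(frame.frame_id if frame.frame_id is not None else str(i))
        s_m.append(sasa(frame.subset(in_ref), probe, n_points, radii)[1])
        s_t.append(sasa(frame.subset(~in_ref), probe, n_points, radii)[1])
        s_all.append(sasa(frame, probe, n_points, radii)[1])
    return SasaSeries(ids, np.array(s_m), np.array(s_t), np.array(s_all), probe)


# -- pairwise interaction energies ---------------------------------------


@dataclass
class EnergyParams:
    """Per-atom-type nonbonded parameters for group-group energies.

    ``charges`` maps (res_name, atom_name) or atom_name to a partial
    charge (e); ``lj`` maps the same keys to (Rmin/2 in A, epsilon in
    kcal/mol).  The electrostatic term uses a distance-dependent
    dielectric eps(r) = eps0 * r, i.e. E = k q_i q_j / (eps0 r^2).
    """

    charges: Mapping
    lj: Mapping
    eps0: float = 1.0
    coulomb: float = COULOMB_CONSTANT
    cutoff: float = 12.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def _lookup(self, table: Mapping, resname: str, atom: str):
        for key in ((resname, atom), atom):
            if key in table:
                return table[key]
        raise KeyError(f"no parameters for atom {atom!r} in residue {resname!r}")

    def atom_params(self, cs: CoordinateSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        q = np.empty(len(cs))
        rmin_half = np.empty(len(cs))
        eps = np.empty(len(cs))
        for i, (rn, an) in enumerate(zip(cs.resname, cs.atom_name)):
            q[i] = self._lookup(self.charges, str(rn), str(an))
            rmin_half[i], eps[i] = self._lookup(self.lj, str(rn), str(an))
        if np.any(eps < 0):
            raise ValueError("negative Lennard-Jones epsilon")
        return q, rmin_half, eps

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "EnergyParams":
        df = pd.read_csv(path)
        charges, lj = {}, {}
        for _, row in df.iterrows():
            key = (
                (str(row["res_name"]), str(row["atom_name"]))
                if "res_name" in df.columns and pd.notna(row.get("res_name"))
                else str(row["atom_name"])
            )
            charges[key] = float(row["charge"])
            lj[key] = (float(row["rmin_half"]), float(row["epsilon"]))
        return cls(charges, lj, **kwargs)


def pairwise_interaction_energy(
    group_a: CoordinateSet,
    group_b: CoordinateSet,
    params: EnergyParams,
) -> tuple[float, float]:
    """(electrostatic, Lennard-Jones) energy between two atom groups, kcal/mol.

    E_elec = sum k q_i q_j / (eps0 r_ij^2)        (eps(r) = eps0 * r)
    E_LJ   = sum eps_ij [(Rmin_ij/r)^12 - 2 (Rmin_ij/r)^6]

    with Lorentz combination on Rmin (Rmin_ij = Rmin_i/2 + Rmin_j/2 summed)
    and geometric combination on epsilon.  Pairs beyond the cutoff are
    skipped; overlapping atoms (r < 0.1 A) raise.
    """
    qa, ra, ea = params.atom_params(group_a)
    qb, rb, eb = params.atom_params(group_b)
    r = cdist(group_a.xyz, group_b.xyz)
    if np.any(r < 0.1):
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise ValueError(
            f"overlapping atoms (r = {r[i, j]:.3f} A < 0.1 A): "
            f"a[{i}] {group_a.atom_name[i]} / b[{j}] {group_b.atom_name[j]}"
        )
    within = r <= params.cutoff
    if not np.any(within):
        return 0.0, 0.0
    rr = r[within]
    qq = np.outer(qa, qb)[within]
    e_elec = float(np.sum(params.coulomb * qq / (params.eps0 * rr**2)))
    rmin_ij = (ra[:, None] + rb[None, :])[within]
    eps_ij = np.sqrt(np.outer(ea, eb))[within]
    ratio6 = (rmin_ij / rr) ** 6
    e_lj = float(np.sum(eps_ij * (ratio6**2 - 2.0 * ratio6)))
    return e_elec, e_lj
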