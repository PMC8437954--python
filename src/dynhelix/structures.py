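"""Rigid-body superposition, hinge angles and interface conservation.

Implements the measurement methodology used to compare dynamin conformers:
least-squares (Kabsch) superposition of paired Cα atoms, extraction of a
rotation angle/axis/screw translation, the two-stage hinge-angle protocol
(align on one domain, measure the residual rotation of another), and
interface conservation between chain pairs (contact sets, their Jaccard
similarity, and an interface RMSD).

Coordinate files are read through gemmi (PDB and mmCIF).  All coordinates
are Ångström.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AtomicStructure",
    "DomainDefinition",
    "RigidTransform",
    "read_structure",
    "write_pdb",
    "superpose",
    "hinge_angle",
    "HingeResult",
    "interface_conservation",
    "InterfaceReport",
    "load_domains",
    "DEFAULT_DOMAINS_FILE",
]

DEFAULT_DOMAINS_FILE = Path(__file__).parent / "data" / "dynamin1_domains.toml"


@dataclass
class AtomicStructure:
    """Flat atom table: parallel arrays plus (x, y, z) coordinates in Å."""

    chain: np.ndarray
    resnum: np.ndarray
    resname: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    xyz: np.ndarray
    icode: np.ndarray | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chain = np.asarray(self.chain, dtype=object)
        self.resnum = np.asarray(self.resnum, dtype=int)
        self.resname = np.asarray(self.resname, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.icode is None:
            self.icode = np.asarray([""] * len(self.resnum), dtype=object)
        if self.xyz.ndim != 2 or self.xyz.shape != (len(self.resnum), 3):
            raise ValueError("xyz must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.resnum)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(c)
        return list(seen)

    def keys(self) -> list[tuple]:
        """(chain, resnum, icode, atom_name) identity of each atom."""
        return list(zip(self.chain, self.resnum, self.icode, self.atom_name))

    def mask(
        self,
        chain: str | None = None,
        domain: "DomainDefinition | None" = None,
        atom_names: tuple[str, ...] | None = None,
    ) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if chain is not None:
            m &= self.chain == chain
        if domain is not None:
            m &= domain.contains(self.resnum)
            if domain.chain is not None:
                m &= self.chain == domain.chain
        if atom_names is not None:
            m &= np.isin(self.atom_name.astype(str), atom_names)
        return m

    def select(self, **kwargs) -> "AtomicStructure":
        m = self.mask(**kwargs)
        return AtomicStructure(
            chain=self.chain[m],
            resnum=self.resnum[m],
            resname=self.resname[m],
            atom_name=self.atom_name[m],
            element=self.element[m],
            xyz=self.xyz[m],
            icode=self.icode[m],
            label=self.label,
            meta=dict(self.meta),
        )

    def transformed(self, t: "RigidTransform") -> "AtomicStructure":
        out = self.select()
        out.xyz = t.apply(self.xyz)
        return out


@dataclass(frozen=True)
class DomainDefinition:
    """Named set of inclusive residue ranges (author numbering)."""

    name: str
    ranges: tuple[tuple[int, int], ...]
    chain: str | None = None

    def __post_init__(self) -> None:
        spans = sorted(self.ranges)
        for (a, b) in spans:
            if a > b:
                raise ValueError(f"range {a}-{b} in domain {self.name} is inverted")
        for (_, b1), (a2, _) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError(f"overlapping ranges in domain {self.name}")
        object.__setattr__(self, "ranges", tuple(tuple(r) for r in spans))

    def contains(self, resnum) -> np.ndarray:
        resnum = np.asarray(resnum)
        m = np.zeros(resnum.shape, dtype=bool)
        for a, b in self.ranges:
            m |= (resnum >= a) & (resnum <= b)
        return m


def load_domains(path: str | Path | None = None) -> dict[str, DomainDefinition]:
    """Load domain definitions from a TOML file (defaults shipped for dynamin 1)."""
    import tomllib

    path = Path(path) if path is not None else DEFAULT_DOMAINS_FILE
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    out = {}
    for name, entry in raw.items():
        out[name] = DomainDefinition(
            name=name,
            ranges=tuple(tuple(r) for r in entry["ranges"]),
            chain=entry.get("chain"),
        )
    return out


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x → R x + t, with derived angle/axis/screw."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length-3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("improper rotation (reflection)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.rotation.T + self.translation

    @property
    def angle_deg(self) -> float:
        """Rotation angle in [0, 180]°."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))

    @property
    def axis(self) -> np.ndarray:
        """Unit rotation axis; sign chosen so the screw translation is ≥ 0."""
        from scipy.spatial.transform import Rotation

        rotvec = Rotation.from_matrix(self.rotation).as_rotvec()
        n = np.linalg.norm(rotvec)
        if n < 1e-12:
            return np.array([0.0, 0.0, 1.0])
        ax = rotvec / n
        if float(ax @ self.translation) < 0:
            ax = -ax
        return ax

    @property
    def screw_translation(self) -> float:
        """Translation component along the rotation axis (≥ 0 by convention), Å."""
        return abs(float(self.axis @ self.translation))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


# -- I/O --------------------------------------------------------------------


def read_structure(path: str | Path, fmt: str | None = None) -> AtomicStructure:
    """Read a PDB or mmCIF file into an :class:`AtomicStructure`.

    Only ATOM records (polymer atoms) are kept; HETATM are dropped; for
    alternate locations the highest-occupancy conformer is kept.  A warning
    is emitted when insertion codes are present (they are preserved and
    used in atom pairing).
    """
    import gemmi

    path = Path(path)
    if fmt is None:
        fmt = "mmCIF" if path.suffix.lower() in (".cif", ".mmcif") else "PDB"
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    st.setup_entities()
    model = st[0]
    rows: list[tuple] = []
    any_icode = False
    for ch in model:
        for res in ch:
            if res.het_flag == "H":
                continue
            best: dict[str, object] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:  # type: ignore[union-attr]
                    best[atom.name] = atom
            icode = (res.seqid.icode or "").strip()
            if icode:
                any_icode = True
            for atom in best.values():
                rows.append(
                    (
                        ch.name,
                        res.seqid.num,
                        res.name,
                        atom.name,  # type: ignore[union-attr]
                        atom.element.name,  # type: ignore[union-attr]
                        atom.pos.x,  # type: ignore[union-attr]
                        atom.pos.y,  # type: ignore[union-attr]
                        atom.pos.z,  # type: ignore[union-attr]
                        icode,
                    )
                )
    if any_icode:
        warnings.warn(f"{path.name}: insertion codes present; kept as residue suffixes")
    if not rows:
        raise ValueError(f"no polymer ATOM records found in {path}")
    cols = list(zip(*rows))
    return AtomicStructure(
        chain=np.array(cols[0], dtype=object),
        resnum=np.array(cols[1], dtype=int),
        resname=np.array(cols[2], dtype=object),
        atom_name=np.array(cols[3], dtype=object),
        element=np.array(cols[4], dtype=object),
        xyz=np.column_stack([cols[5], cols[6], cols[7]]).astype(float),
        icode=np.array(cols[8], dtype=object),
        label=path.stem,
    )


def write_pdb(structure: AtomicStructure, path: str | Path) -> None:
    """Write the atom table as a PDB file (via gemmi)."""
    import gemmi

    # gemmi's add_* methods copy by value, so build bottom-up: atoms into a
    # residue, residues into a chain, chains into the model last.
    groups: dict[str, dict[tuple, list[int]]] = {}
    for i in range(len(structure)):
        cname = str(structure.chain[i])
        key = (int(structure.resnum[i]), str(structure.icode[i]), str(structure.resname[i]))
        groups.setdefault(cname, {}).setdefault(key, []).append(i)

    st = gemmi.Structure()
    st.name = structure.label or "dynhelix"
    model = gemmi.Model("1")
    for cname, residues in groups.items():
        chain = gemmi.Chain(cname)
        for (resnum, icode, resname), idxs in residues.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, icode or " ")
            res.het_flag = "A"
            for i in idxs:
                atom = gemmi.Atom()
                atom.name = str(structure.atom_name[i])
                atom.element = gemmi.Element(str(structure.element[i]) or "C")
                atom.pos = gemmi.Position(*structure.xyz[i])
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


# -- superposition ----------------------------------------------------------


def _pair_indices(
    mobile: AtomicStructure,
    reference: AtomicStructure,
    chain_map: dict[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of atoms paired by (mapped chain, resnum, icode, atom name).

    Raises if a paired residue's name differs between structures — a guard
    against shuffled or shifted residue numbering silently degrading the
    superposition.
    """
    ref_index = {k: i for i, k in enumerate(reference.keys())}
    im, ir = [], []
    for i, (c, rn, ic, an) in enumerate(mobile.keys()):
        key = (chain_map.get(c, c) if chain_map else c, rn, ic, an)
        j = ref_index.get(key)
        if j is not None:
            if mobile.resname[i] != reference.resname[j]:
                raise ValueError(
                    f"residue identity mismatch at {key}: "
                    f"{mobile.resname[i]} vs {reference.resname[j]} — "
                    "check residue numbering"
                )
            im.append(i)
            ir.append(j)
    return np.asarray(im, dtype=int), np.asarray(ir, dtype=int)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Least-squares proper rotation+translation taking P onto Q."""
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) atom selection")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return RigidTransform(rotation=R, translation=t)


def superpose(
    mobile: AtomicStructure,
    reference: AtomicStructure,
    domain: DomainDefinition | None = None,
    chain: str | None = None,
    ca_only: bool = True,
    chain_map: dict[str, str] | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Atoms are paired by chain (optionally remapped), residue number,
    insertion code and atom name; Cα only by default.  Returns the
    transform and the RMSD (Å) over the paired selection.  A proper
    rotation (det +1) is always returned.
    """
    names = ("CA",) if ca_only else None
    msel = mobile.select(chain=chain, domain=domain, atom_names=names)
    rsel = reference.select(
        chain=chain_map.get(chain, chain) if (chain_map and chain) else chain,
        domain=domain,
        atom_names=names,
    )
    im, ir = _pair_indices(msel, rsel, chain_map)
    if len(im) < 3:
        raise ValueError(f"only {len(im)} paired atoms; need at least 3")
    P = msel.xyz[im]
    Q = rsel.xyz[ir]
    t = _kabsch(P, Q)
    rmsd = float(np.sqrt(((t.apply(P) - Q) ** 2).sum(axis=1).mean()))
    return t, rmsd


@dataclass(frozen=True)
class HingeResult:
    angle_deg: float
    axis: np.ndarray
    screw_translation_A: float
    align_rmsd_A: float
    measure_rmsd_A: float


def hinge_angle(
    s1: AtomicStructure,
    s2: AtomicStructure,
    align_domain: DomainDefinition,
    measure_domain: DomainDefinition,
    ca_only: bool = True,
    chain_map: dict[str, str] | None = None,
) -> HingeResult:
    """Hinge rotation of ``measure_domain`` between two conformers.

    Protocol: superpose s2 onto s1 using ``align_domain`` (removing the
    global difference), then superpose the ``measure_domain`` of the
    aligned s2 onto that of s1; the second rotation's angle is the hinge
    angle.  Invariant under global rigid motions of either structure.
    """
    for dom, s, which in ((align_domain, s1, "s1"), (measure_domain, s1, "s1"),
                          (align_domain, s2, "s2"), (measure_domain, s2, "s2")):
        if not dom.contains(s.resnum).any():
            raise ValueError(f"domain {dom.name} matches no residues in {which}")
    t_align, rmsd_align = superpose(s2, s1, domain=align_domain, ca_only=ca_only, chain_map=chain_map)
    s2_aligned = s2.transformed(t_align)
    t_measure, rmsd_measure = superpose(
        s2_aligned, s1, domain=measure_domain, ca_only=ca_only, chain_map=chain_map
    )
    return HingeResult(
        angle_deg=t_measure.angle_deg,
        axis=t_measure.axis,
        screw_translation_A=t_measure.screw_translation,
        align_rmsd_A=rmsd_align,
        measure_rmsd_A=rmsd_measure,
    )


# -- interfaces -------------------------------------------------------------


@dataclass(frozen=True)
class InterfaceReport:
    contacts_1: frozenset
    contacts_2: frozenset
    jaccard: float | None
    interface_rmsd_A: float | None


def _contact_set(
    s: AtomicStructure, chain_a: str, chain_b: str, cutoff: float
) -> frozenset[tuple[int, int]]:
    """Residue pairs (resnum_a, resnum_b) with any Cα–Cα distance ≤ cutoff."""
    from scipy.spatial import cKDTree

    a = s.select(chain=chain_a, atom_names=("CA",))
    b = s.select(chain=chain_b, atom_names=("CA",))
    if len(a) == 0 or len(b) == 0:
        return frozenset()
    pairs = cKDTree(a.xyz).query_ball_tree(cKDTree(b.xyz), r=cutoff)
    out = set()
    for i, js in enumerate(pairs):
        for j in js:
            out.add((int(a.resnum[i]), int(b.resnum[j])))
    return frozenset(out)


def interface_conservation(
    s1: AtomicStructure,
    s2: AtomicStructure,
    chain_pair_1: tuple[str, str],
    chain_pair_2: tuple[str, str] | None = None,
    cutoff_A: float = 10.0,
) -> InterfaceReport:
    """Conservation of a chain–chain interface between two structures.

    Contacts are residue pairs across the chain pair with Cα–Cα distance
    ≤ cutoff.  The Jaccard similarity compares the two contact sets
    (``None`` when both are empty).  The interface RMSD is computed over
    Cα atoms of the union of contacting residues after superposing s2 on
    s1 using the first chain of the pair.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff must be positive")
    if chain_pair_2 is None:
        chain_pair_2 = chain_pair_1
    for ch, s, which in ((chain_pair_1[0], s1, "s1"), (chain_pair_1[1], s1, "s1"),
                         (chain_pair_2[0], s2, "s2"), (chain_pair_2[1], s2, "s2")):
        if ch not in s.chains:
            raise ValueError(f"chain {ch} not present in {which}")
    c1 = _contact_set(s1, *chain_pair_1, cutoff_A)
    c2 = _contact_set(s2, *chain_pair_2, cutoff_A)
    union = c1 | c2
    jaccard = None if not union else len(c1 & c2) / len(union)
    rmsd = None
    if union:
        chain_map = {chain_pair_2[0]: chain_pair_1[0], chain_pair_2[1]: chain_pair_1[1]}
        t, _ = superpose(s2, s1, chain=chain_pair_2[0], ca_only=True, chain_map=chain_map)
        s2a = s2.transformed(t)
        res_a = sorted({p[0] for p in union})
        res_b = sorted({p[1] for p in union})
        dom_a = _ranges_of(res_a)
        dom_b = _ranges_of(res_b)
        sel1 = np.concatenate(
            [
                np.where(s1.mask(chain=chain_pair_1[0], atom_names=("CA",)) & dom_a.contains(s1.resnum))[0],
                np.where(s1.mask(chain=chain_pair_1[1], atom_names=("CA",)) & dom_b.contains(s1.resnum))[0],
            ]
        )
        sel2 = np.concatenate(
            [
                np.where(s2a.mask(chain=chain_pair_2[0], atom_names=("CA",)) & dom_a.contains(s2a.resnum))[0],
                np.where(s2a.mask(chain=chain_pair_2[1], atom_names=("CA",)) & dom_b.contains(s2a.resnum))[0],
            ]
        )
        # pair by (mapped chain, resnum) within the interface selection
        key1 = {
            (str(s1.chain[i]), int(s1.resnum[i])): i for i in sel1
        }
        chain_map_12 = {chain_pair_1[0]: chain_pair_2[0], chain_pair_1[1]: chain_pair_2[1]}
        d2 = []
        for j in sel2:
            key = (str(s2a.chain[j]), int(s2a.resnum[j]))
            back = (
                {v: k for k, v in chain_map_12.items()}.get(key[0], key[0]),
                key[1],
            )
            i = key1.get(back)
            if i is not None:
                d2.append(((s2a.xyz[j] - s1.xyz[i]) ** 2).sum())
        if d2:
            rmsd = float(np.sqrt(np.mean(d2)))
    return InterfaceReport(contacts_1=c1, contacts_2=c2, jaccard=jaccard, interface_rmsd_A=rmsd)


def _ranges_of(resnums: list[int]) -> DomainDefinition:
    """Collapse a sorted residue list into a DomainDefinition of ranges."""
    ranges = []
    start = prev = resnums[0]
    for r in resnums[1:]:
        if r == prev + 1:
            prev = r
            continue
        ranges.append((start, prev))
        start = prev = r
    ranges.append((start, prev))
    return DomainDefinition(name="interface", ranges=tuple(ranges))
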