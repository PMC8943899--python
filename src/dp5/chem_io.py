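"""Structure, shift-table, peak-list and annotation I/O.

Molecules are held in a light container (elements, bonds, conformers) that is
decoupled from RDKit so that every downstream per-atom array shares one stable
0-based atom ordering.  RDKit does the actual SDF/SMILES/InChI parsing and
writing; SDF's 1-based indices are translated at this boundary.

Units: coordinates in Angstrom, energies in kJ/mol (kcal/mol and Hartree are
accepted with explicit conversion), shifts in ppm.  Inputs declared as
shielding constants are converted to shifts via a user-supplied scalar
reference shielding.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .exceptions import ConsistencyError, DomainError, FormatError

log = logging.getLogger(__name__)

ENERGY_CONVERSIONS = {
    "kJ/mol": 1.0,
    "kcal/mol": 4.184,
    "hartree": 2625.499_639,
}

#: deterministic seed used when a bare SMILES/InChI must be embedded in 3D
EMBED_SEED = 20220225

SHIFT_TAG_PREFIX = "DP5_SHIFTS"
ENERGY_TAG = "DP5_ENERGY_KJMOL"
ATOM_PROB_TAG = "DP5_ATOM_PROBS"


@dataclass
class Conformer:
    """One 3D geometry of a molecule with optional calculated carbon shifts."""

    coordinates: np.ndarray  # (n_atoms, 3), Angstrom
    relative_energy: float = 0.0  # kJ/mol, minimum conformer = 0
    calculated_shifts: dict[int, float] | None = None  # atom_index -> ppm


@dataclass
class Molecule:
    molecule_id: str
    elements: list[str]  # per-atom element symbols, explicit hydrogens
    bonds: list[tuple[int, int, float]]  # (i, j, order), 0-based
    conformers: list[Conformer] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        n = len(self.elements)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise DomainError(
                    f"{self.molecule_id}: bond ({i},{j}) outside 0..{n - 1}"
                )
        for c, conf in enumerate(self.conformers):
            conf.coordinates = np.asarray(conf.coordinates, dtype=float)
            if conf.coordinates.shape != (n, 3):
                raise DomainError(
                    f"{self.molecule_id}: conformer {c} has "
                    f"{conf.coordinates.shape[0]} coordinates for {n} atoms"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def carbon_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.elements) if e == "C"], dtype=int)

    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for e in self.elements if e != "H")

    def carbon_shifts(self, conformer_index: int) -> np.ndarray:
        """Calculated shifts of all carbons, in ascending atom-index order."""
        conf = self.conformers[conformer_index]
        if conf.calculated_shifts is None:
            raise DomainError(
                f"{self.molecule_id}: conformer {conformer_index} has no shifts"
            )
        try:
            return np.array([conf.calculated_shifts[i] for i in self.carbon_indices])
        except KeyError as exc:
            raise DomainError(
                f"{self.molecule_id}: carbon atom {exc.args[0]} has no shift"
            ) from exc

    def relative_energies(self) -> np.ndarray:
        return np.array([c.relative_energy for c in self.conformers])


@dataclass
class PeakList:
    """Experimental 13C peak positions in ppm, sorted ascending."""

    shifts: np.ndarray
    multiplicities: np.ndarray | None = None  # equivalent-carbon counts

    def __post_init__(self) -> None:
        shifts = np.asarray(self.shifts, dtype=float)
        if shifts.size == 0:
            raise DomainError("peak list is empty")
        if not np.all(np.isfinite(shifts)):
            raise DomainError("peak list contains non-finite values")
        mult = self.multiplicities
        if mult is None:
            mult = np.ones(shifts.size, dtype=int)
        mult = np.asarray(mult, dtype=int)
        order = np.lexsort((mult, shifts))
        self.shifts = shifts[order]
        self.multiplicities = mult[order]

    @property
    def n_slots(self) -> int:
        return int(self.multiplicities.sum())


@dataclass
class AtomAnnotation:
    atom_index: int
    element: str
    probability: float
    assigned_peak: float | None
    scaled_error: float | None

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ConsistencyError(
                f"atom {self.atom_index}: probability {self.probability} not in [0,1]"
            )


# ---------------------------------------------------------------------------
# RDKit conversion


_BOND_ORDERS = {
    1.0: Chem.BondType.SINGLE,
    1.5: Chem.BondType.AROMATIC,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
}


def molecule_to_rdkit(molecule: Molecule, conformer_index: int = 0) -> Chem.Mol:
    rw = Chem.RWMol()
    for element in molecule.elements:
        atom = Chem.Atom(element)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j, order in molecule.bonds:
        rw.AddBond(int(i), int(j), _BOND_ORDERS.get(float(order), Chem.BondType.SINGLE))
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, catchErrors=True)
    conf = Chem.Conformer(molecule.n_atoms)
    for i, xyz in enumerate(molecule.conformers[conformer_index].coordinates):
        conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
    mol.AddConformer(conf, assignId=True)
    mol.SetProp("_Name", molecule.molecule_id)
    return mol


def rdkit_to_molecule(
    mol: Chem.Mol, molecule_id: str, provenance: str = ""
) -> Molecule:
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in mol.GetBonds()
    ]
    conformers = [
        Conformer(coordinates=np.array(c.GetPositions(), dtype=float))
        for c in mol.GetConformers()
    ]
    molecule = Molecule(
        molecule_id=molecule_id,
        elements=elements,
        bonds=bonds,
        conformers=conformers,
        provenance=provenance,
    )
    if len(molecule.carbon_indices) == 0:
        raise DomainError(f"{molecule_id}: no carbon atoms; 13C analysis impossible")
    return molecule


def _embed(mol: Chem.Mol, seed: int) -> Chem.Mol:
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise DomainError("3D embedding failed")
    return mol


def _parse_shift_tags(mol: Chem.Mol, n_carbons: int, carbon_idx: np.ndarray):
    """Collect DP5_SHIFTS[_k] props -> {k: {atom_index: ppm}}; None if absent."""
    out: dict[int, dict[int, float]] = {}
    for name in mol.GetPropNames():
        if not name.startswith(SHIFT_TAG_PREFIX):
            continue
        suffix = name[len(SHIFT_TAG_PREFIX):]
        k = int(suffix.lstrip("_")) if suffix else 0
        values = [float(v) for v in mol.GetProp(name).split()]
        if len(values) != n_carbons:
            raise FormatError(
                f"{name}: {len(values)} shifts for {n_carbons} carbons"
            )
        out[k] = {int(i): v for i, v in zip(carbon_idx, values)}
    return out or None


def read_structure(
    source: str | Path,
    format: str,
    embed_seed: int = EMBED_SEED,
) -> Molecule | list[Molecule]:
    """Read candidate structure(s).

    ``format`` is one of ``sdf``, ``smiles``, ``inchi``.  SMILES/InChI inputs
    carry no geometry, so a single 3D conformer is embedded deterministically
    (seed logged).  An SDF may contain several records; consecutive records
    with identical atom and bond sequences are merged into one molecule with
    multiple conformers, and a multi-molecule SDF returns a list.
    """
    if format in ("smiles", "inchi"):
        text = str(source)
        mol = (
            Chem.MolFromSmiles(text)
            if format == "smiles"
            else Chem.MolFromInchi(text)
        )
        if mol is None:
            raise FormatError(f"could not parse {format} input {text!r}")
        log.info("embedding single conformer for %r (seed=%d)", text, embed_seed)
        mol = _embed(mol, embed_seed)
        return rdkit_to_molecule(mol, molecule_id=text, provenance=text)

    if format != "sdf":
        raise FormatError(f"unknown structure format {format!r}")

    path = Path(source)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    molecules: list[Molecule] = []
    current: Molecule | None = None
    current_key = None
    for rec_no, mol in enumerate(supplier):
        if mol is None:
            raise FormatError(f"{path}: SDF record {rec_no + 1} failed to parse")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        key = (
            name,
            tuple(a.GetSymbol() for a in mol.GetAtoms()),
            tuple(sorted(
                (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
            )),
        )
        parsed = rdkit_to_molecule(
            mol, molecule_id=name or f"{path.stem}_{rec_no}", provenance=str(path)
        )
        conf = parsed.conformers[0]
        shift_tags = _parse_shift_tags(
            mol, len(parsed.carbon_indices), parsed.carbon_indices
        )
        if shift_tags is not None:
            conf.calculated_shifts = shift_tags[min(shift_tags)]
        if mol.HasProp(ENERGY_TAG):
            conf.relative_energy = float(mol.GetProp(ENERGY_TAG))
        if current is not None and key == current_key:
            current.conformers.append(conf)
        else:
            if current is not None:
                molecules.append(current)
            current, current_key = parsed, key
    if current is not None:
        molecules.append(current)
    if not molecules:
        raise FormatError(f"{path}: no records")
    for m in molecules:
        energies = m.relative_energies()
        for c, e in zip(m.conformers, energies - energies.min()):
            c.relative_energy = float(e)
    return molecules[0] if len(molecules) == 1 else molecules


def write_structure(molecule: Molecule, path: str | Path) -> None:
    """Write one SDF record per conformer, with shift/energy property tags."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    carbon_idx = molecule.carbon_indices
    for k in range(len(molecule.conformers)):
        mol = molecule_to_rdkit(molecule, conformer_index=k)
        conf = molecule.conformers[k]
        if conf.calculated_shifts is not None:
            mol.SetProp(
                f"{SHIFT_TAG_PREFIX}_{k}",
                " ".join(f"{conf.calculated_shifts[i]:.6f}" for i in carbon_idx),
            )
        mol.SetProp(ENERGY_TAG, f"{conf.relative_energy:.6f}")
        writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# Shift tables


def read_shift_table(
    path: str | Path,
    molecule: Molecule,
    energy_unit: str = "kJ/mol",
    shieldings: bool = False,
    reference_shielding: float | None = None,
) -> Molecule:
    """Populate a molecule's conformers with calculated shifts and energies.

    CSV columns: ``conformer_id, atom_index, shift_ppm[, energy_kjmol]``.
    Rows with an empty ``atom_index`` carry the conformer's energy; shift rows
    must cover every carbon exactly once.  Energies are shifted so the minimum
    is zero.  If the molecule holds a single geometry but the table lists k
    conformers, the geometry is replicated (shifts may come from re-optimised
    geometries the caller chose not to supply).
    """
    if shieldings and reference_shielding is None:
        raise DomainError("shielding input requires a reference_shielding")
    scale = ENERGY_CONVERSIONS.get(energy_unit)
    if scale is None:
        raise DomainError(f"unknown energy unit {energy_unit!r}")

    carbons = set(int(i) for i in molecule.carbon_indices)
    shifts: dict[str, dict[int, float]] = {}
    energies: dict[str, float] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        for line_no, row in enumerate(reader, start=2):
            conf_id = (row.get("conformer_id") or "").strip()
            if not conf_id:
                raise FormatError(f"{path}:{line_no}: missing conformer_id")
            atom_raw = (row.get("atom_index") or "").strip()
            if atom_raw:
                atom = int(atom_raw)
                if atom < 0 or atom >= molecule.n_atoms:
                    raise FormatError(
                        f"{path}:{line_no}: atom index {atom} out of range"
                    )
                if atom not in carbons:
                    raise DomainError(
                        f"{path}:{line_no}: atom {atom} is not a carbon"
                    )
                value = float(row["shift_ppm"])
                if shieldings:
                    value = reference_shielding - value
                table = shifts.setdefault(conf_id, {})
                if atom in table:
                    raise FormatError(
                        f"{path}:{line_no}: duplicate shift for conformer "
                        f"{conf_id}, atom {atom}"
                    )
                table[atom] = value
            else:
                raw = (row.get("energy_kjmol") or row.get("shift_ppm") or "").strip()
                if not raw:
                    raise FormatError(f"{path}:{line_no}: energy row without value")
                energies[conf_id] = float(raw) * scale

    if not shifts:
        raise FormatError(f"{path}: no shift rows")
    conf_ids = sorted(shifts, key=lambda s: (len(s), s))
    for conf_id in conf_ids:
        missing = carbons - set(shifts[conf_id])
        if missing:
            raise DomainError(
                f"{path}: conformer {conf_id} missing shifts for carbons "
                f"{sorted(missing)}"
            )

    if len(molecule.conformers) == 1 and len(conf_ids) > 1:
        base = molecule.conformers[0]
        molecule.conformers = [
            Conformer(coordinates=base.coordinates.copy()) for _ in conf_ids
        ]
    if len(molecule.conformers) != len(conf_ids):
        raise DomainError(
            f"{path}: table has {len(conf_ids)} conformers, molecule has "
            f"{len(molecule.conformers)}"
        )

    e = np.array([energies.get(cid, 0.0) for cid in conf_ids])
    e -= e.min()
    for conf, cid, energy in zip(molecule.conformers, conf_ids, e):
        conf.calculated_shifts = dict(sorted(shifts[cid].items()))
        conf.relative_energy = float(energy)
    return molecule


def read_peak_list(path: str | Path) -> PeakList:
    """Read a peak list: one ppm per line, or CSV ``shift_ppm[,count]``."""
    shifts: list[float] = []
    counts: list[int] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.lower().startswith("shift_ppm"):
                continue  # optional CSV header
            parts = [p.strip() for p in line.split(",")]
            try:
                shifts.append(float(parts[0]))
                counts.append(int(parts[1]) if len(parts) > 1 and parts[1] else 1)
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: not numeric: {line!r}") from exc
    if not shifts:
        raise FormatError(f"{path}: empty peak list")
    return PeakList(shifts=np.array(shifts), multiplicities=np.array(counts))


def write_peak_list(peaks: PeakList, path: str | Path) -> None:
    with open(path, "w") as handle:
        for shift, mult in zip(peaks.shifts, peaks.multiplicities):
            if mult == 1:
                handle.write(f"{shift:.4f}\n")
            else:
                handle.write(f"{shift:.4f},{mult}\n")


# ---------------------------------------------------------------------------
# Annotation export


def write_annotations(result, molecule: Molecule, path: str | Path) -> None:
    """Write per-atom probability annotations: a CSV table plus a tagged SDF.

    The CSV has columns ``atom_index,element,assigned_peak_ppm,
    scaled_error_ppm,atomic_probability``; the SDF copy carries the carbon
    probabilities in a ``DP5_ATOM_PROBS`` property so depiction tools can
    overlay them.
    """
    carbon_idx = molecule.carbon_indices
    probs = np.asarray(result.atomic_probabilities, dtype=float)
    if probs.shape[0] != carbon_idx.shape[0]:
        raise ConsistencyError(
            f"result has {probs.shape[0]} atomic probabilities for "
            f"{carbon_idx.shape[0]} carbons"
        )
    annotations = [
        AtomAnnotation(
            atom_index=int(idx),
            element="C",
            probability=float(p),
            assigned_peak=result.assignment.mapping.get(int(idx)),
            scaled_error=result.scaled_errors.get(int(idx)),
        )
        for idx, p in zip(carbon_idx, probs)
    ]
    path = Path(path)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["atom_index", "element", "assigned_peak_ppm",
             "scaled_error_ppm", "atomic_probability"]
        )
        for ann in annotations:
            writer.writerow([
                ann.atom_index,
                ann.element,
                "" if ann.assigned_peak is None else f"{ann.assigned_peak:.4f}",
                "" if ann.scaled_error is None else f"{ann.scaled_error:.4f}",
                f"{ann.probability:.6f}",
            ])
    sdf_path = path.with_suffix(".sdf")
    mol = molecule_to_rdkit(molecule, conformer_index=0)
    mol.SetProp(ATOM_PROB_TAG, " ".join(f"{p:.6f}" for p in probs))
    writer = Chem.SDWriter(str(sdf_path))
    writer.SetKekulize(False)
    writer.write(mol)
    writer.close()


def read_annotated_probabilities(path: str | Path) -> np.ndarray:
    """Read back the carbon probabilities from a tagged SDF."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mol = next(iter(supplier))
    if mol is None or not mol.HasProp(ATOM_PROB_TAG):
        raise FormatError(f"{path}: no {ATOM_PROB_TAG} property")
    return np.array([float(v) for v in mol.GetProp(ATOM_PROB_TAG).split()])
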