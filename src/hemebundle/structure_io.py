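"""Multi-model structure I/O and atom selection.

Reads and writes multi-model PDB files of peptide-porphyrin conjugates,
including nonstandard residues (Aib, Dab) and the deuteroporphyrin
hetero-group, validates atom-identity consistency across models, and
provides the selection and report-writing plumbing the descriptor layer
builds on.  Parsing and serialization of the PDB format itself are
delegated to biotite; this module owns the ensemble container, the
topology registry for nonstandard residues, and the consistency checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    ConsistencyError,
    EmptySelectionError,
    ParseError,
    TopologyError,
    ValidationError,
)

__all__ = [
    "AtomRecord",
    "Model",
    "StructureEnsemble",
    "PorphyrinTopology",
    "SelectionSpec",
    "default_topology",
    "load_topology_registry",
    "read_ensemble",
    "write_ensemble",
    "select_atoms",
    "write_report",
    "read_report",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom of one model.

    ``identity`` (chain, residue number, atom name) is the key used to
    check that all models of an ensemble describe the same molecule.
    """

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    is_hetero: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError(
                f"atom {self.atom_name}: position must be a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)
        if self.residue_number < 1:
            raise ValidationError(
                f"atom {self.atom_name}: residue_number must be >= 1"
            )

    @property
    def identity(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)


@dataclass
class Model:
    """An ordered list of atoms for one member of the ensemble."""

    index: int
    atoms: list[AtomRecord]

    def __post_init__(self):
        if self.index < 1:
            raise ValidationError("model index must be >= 1")
        idents = [a.identity for a in self.atoms]
        if len(set(idents)) != len(idents):
            dup = next(i for i in idents if idents.count(i) > 1)
            raise ValidationError(f"duplicate atom identity {dup} in model {self.index}")

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def identities(self) -> list[tuple[str, int, str]]:
        return [a.identity for a in self.atoms]

    def find(self, chain_id: str, residue_number: int, atom_name: str) -> AtomRecord:
        for a in self.atoms:
            if a.identity == (chain_id, residue_number, atom_name):
                return a
        raise KeyError((chain_id, residue_number, atom_name))


@dataclass
class PorphyrinTopology:
    """Names of the porphyrin macrocycle atoms and their ring positions.

    Ring carbon positions follow the 1-24 macrocycle numbering: pyrrole
    nitrogens N21-N24, meso carbons at positions 5, 10, 15 and 20,
    beta-pyrrole substituent positions 2, 3, 7, 8, 12, 13, 17 and 18.
    The deuteroporphyrin propionates sit at positions 2 and 18 and are
    the peptide anchoring points.
    """

    ring_atom_names: list[str]
    meso_positions: dict[int, str]
    substituent_positions: dict[int, list[str]]
    propionyl_attachment: dict[int, list[str]]
    metal_atom_name: str = "CO"
    residue_name: str = "DPX"
    metal_residue_name: str = "CO"

    def __post_init__(self):
        if len(self.ring_atom_names) != 24:
            raise TopologyError(
                f"macrocycle needs 24 ring atom names, got {len(self.ring_atom_names)}"
            )
        for n in ("N21", "N22", "N23", "N24"):
            if n not in self.ring_atom_names:
                raise TopologyError(f"pyrrole nitrogen {n} missing from ring atoms")
        for pos in (2, 18):
            if pos not in self.propionyl_attachment:
                raise TopologyError(f"propionyl attachment position {pos} unmapped")


def default_topology() -> PorphyrinTopology:
    """Topology for the idealized deuteroporphyrin used by the generator.

    Macrocycle carbons are named C1..C20; pyrrole nitrogens N21..N24.
    Methyl substituents (positions 3, 8, 13, 17) are CM<pos>; the deutero
    positions 7 and 12 carry ring protons only; propionyl methylene
    carbons at positions 2 and 18 are CAA/CBA and CAD/CBD as in heme
    nomenclature.
    """
    return PorphyrinTopology(
        ring_atom_names=[f"C{i}" for i in range(1, 21)]
        + ["N21", "N22", "N23", "N24"],
        meso_positions={5: "C5", 10: "C10", 15: "C15", 20: "C20"},
        substituent_positions={
            2: ["CAA", "CBA"],
            3: ["CM3"],
            7: ["H7"],
            8: ["CM8"],
            12: ["H12"],
            13: ["CM13"],
            17: ["CM17"],
            18: ["CAD", "CBD"],
        },
        propionyl_attachment={2: ["CAA", "CBA"], 18: ["CAD", "CBD"]},
        metal_atom_name="CO",
        residue_name="DPX",
        metal_residue_name="CO",
    )


#: residue-name registry: which hetero/nonstandard residue codes the reader
#: accepts and what they are.  User configs extend or override this.
DEFAULT_RESIDUE_REGISTRY: dict[str, str] = {
    "AIB": "nonstandard_aa",   # alpha-aminoisobutyric acid
    "DAB": "nonstandard_aa",   # 2,4-diaminobutyric acid
    "DPX": "porphyrin",        # deuteroporphyrin IX macrocycle
    "CO": "metal",
    "FE": "metal",
    "HOH": "solvent",
    "NH2": "cap",
    "ACE": "cap",
}


def load_topology_registry(path: str | Path) -> dict[str, str]:
    """Read a JSON residue registry ``{residue_name: kind}`` and merge it
    over the defaults."""
    with open(path) as fh:
        user = json.load(fh)
    if not isinstance(user, dict):
        raise ParseError(f"topology registry {path} must be a JSON object")
    registry = dict(DEFAULT_RESIDUE_REGISTRY)
    registry.update({str(k).upper(): str(v) for k, v in user.items()})
    return registry


@dataclass
class StructureEnsemble:
    """Ordered multi-model set of atom records plus porphyrin topology."""

    models: list[Model]
    topology: PorphyrinTopology = field(default_factory=default_topology)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.models:
            raise ValidationError("ensemble needs at least one model")
        idx = [m.index for m in self.models]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("model indices must be strictly increasing")
        self._check_identity()

    def _check_identity(self):
        ref = self.models[0].identities()
        for m in self.models[1:]:
            ids = m.identities()
            if ids != ref:
                missing = set(ref) ^ set(ids)
                detail = f"; differing atoms: {sorted(missing)[:5]}" if missing else \
                    "; same atoms, different order"
                raise ConsistencyError(
                    f"model {m.index} atom identities differ from model "
                    f"{self.models[0].index}{detail}"
                )

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_atoms(self) -> int:
        return len(self.models[0].atoms)

    def coords(self) -> np.ndarray:
        """(n_models, n_atoms, 3) coordinate array."""
        return np.stack([m.coords() for m in self.models])


@dataclass(frozen=True)
class SelectionSpec:
    """Atom selection filter; every ``None`` field means "no filter"."""

    chains: frozenset[str] | None = None
    residue_range: tuple[int, int] | None = None
    atom_names: frozenset[str] | None = None
    hetero: bool | None = None

    @classmethod
    def make(
        cls,
        chains: Iterable[str] | None = None,
        residue_range: tuple[int, int] | None = None,
        atom_names: Iterable[str] | None = None,
        hetero: bool | None = None,
    ) -> "SelectionSpec":
        return cls(
            chains=frozenset(chains) if chains is not None else None,
            residue_range=tuple(residue_range) if residue_range is not None else None,
            atom_names=frozenset(atom_names) if atom_names is not None else None,
            hetero=hetero,
        )

    def matches(self, atom: AtomRecord) -> bool:
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not (lo <= atom.residue_number <= hi):
                return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.hetero is not None and atom.is_hetero != self.hetero:
            return False
        return True


BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> None:
    # cheap structural check so parse failures carry a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError("truncated coordinate record", lineno)
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise ParseError(
                    f"unparseable coordinate field in {rec} record", lineno
                ) from None


def read_ensemble(
    path: str | Path,
    topology_config: Mapping[str, str] | str | Path | None = None,
    topology: PorphyrinTopology | None = None,
) -> StructureEnsemble:
    """Read a multi-model PDB file into a :class:`StructureEnsemble`.

    Parameters
    ----------
    path
        Multi-model PDB file (MODEL/ENDMDL records; HETATM allowed).
    topology_config
        Residue registry extending :data:`DEFAULT_RESIDUE_REGISTRY`:
        either a mapping ``{residue_name: kind}`` or a path to a JSON
        file with that shape.  Needed when the deposited file uses other
        codes for Aib/Dab or the porphyrin.
    topology
        Porphyrin atom-name topology; defaults to the idealized
        deuteroporphyrin of :func:`default_topology`.

    Raises
    ------
    ParseError
        Malformed coordinate record (with line number).
    ConsistencyError
        Atom identities differ across models.
    TopologyError
        Hetero residue name absent from the registry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)

    if topology_config is None:
        registry = dict(DEFAULT_RESIDUE_REGISTRY)
    elif isinstance(topology_config, (str, Path)):
        registry = load_topology_registry(topology_config)
    else:
        registry = dict(DEFAULT_RESIDUE_REGISTRY)
        registry.update({str(k).upper(): str(v) for k, v in topology_config.items()})

    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
        arrays = [pdb.get_structure(model=i) for i in range(1, n_models + 1)]
    except ParseError:
        raise
    except Exception as exc:  # biotite's own parse failures
        raise ParseError(f"could not parse {path}: {exc}") from exc

    models: list[Model] = []
    for i, arr in enumerate(arrays, start=1):
        atoms = []
        for j in range(arr.array_length()):
            name = arr.res_name[j].strip().upper()
            if arr.hetero[j] and name not in registry:
                raise TopologyError(
                    f"hetero residue '{name}' (model {i}) has no topology "
                    "registry entry; supply topology_config"
                )
            atoms.append(
                AtomRecord(
                    chain_id=str(arr.chain_id[j]),
                    residue_number=int(arr.res_id[j]),
                    residue_name=name,
                    atom_name=str(arr.atom_name[j]),
                    element=str(arr.element[j]).capitalize(),
                    position=arr.coord[j].astype(float),
                    is_hetero=bool(arr.hetero[j]),
                )
            )
        models.append(Model(index=i, atoms=atoms))

    return StructureEnsemble(
        models=models,
        topology=topology or default_topology(),
        metadata={"source": str(path)},
    )


def write_ensemble(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB file (0.001 Å precision)."""
    n_at = ensemble.n_atoms
    template = ensemble.models[0]
    arr = struc.AtomArray(n_at)
    for j, a in enumerate(template.atoms):
        arr.chain_id[j] = a.chain_id
        arr.res_id[j] = a.residue_number
        arr.res_name[j] = a.residue_name
        arr.atom_name[j] = a.atom_name
        arr.element[j] = a.element.upper()
        arr.hetero[j] = a.is_hetero
    stack = struc.stack([arr] * ensemble.n_models)
    stack.coord = ensemble.coords()
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def select_atoms(
    ensemble: StructureEnsemble, spec: SelectionSpec
) -> list[list[AtomRecord]]:
    """Apply ``spec`` to every model; order preserved, counts equal.

    Raises :class:`EmptySelectionError` when nothing matches (never an
    empty list — downstream descriptor code must not silently average
    over nothing).
    """
    out = []
    for m in ensemble.models:
        out.append([a for a in m.atoms if spec.matches(a)])
    if not out[0]:
        raise EmptySelectionError(f"selection {spec} matched no atoms")
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {
            "__dataframe__": True,
            "columns": list(map(str, obj.columns)),
            "data": [[_jsonify(v) for v in row] for row in obj.itertuples(index=False)],
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def write_report(
    table: pd.DataFrame | Mapping,
    path: str | Path,
    format: str = "tabular",
    float_precision: int = 6,
) -> None:
    """Serialize a result table.

    ``tabular`` writes TSV with fixed-precision floats and deterministic
    column order; ``structured`` writes JSON that round-trips losslessly
    through :func:`read_report`.
    """
    if table is None or (hasattr(table, "__len__") and len(table) == 0):
        raise ValidationError("refusing to write an empty report")
    path = Path(path)
    if format == "tabular":
        if isinstance(table, Mapping):
            table = pd.DataFrame(
                {"key": list(table.keys()), "value": [_jsonify(v) for v in table.values()]}
            )
        aggregates = table.attrs.get("aggregates") if isinstance(table, pd.DataFrame) else None
        if aggregates:
            # one summary row per family under the per-model rows
            extra = []
            for lab, agg in aggregates.items():
                row = {}
                for col in table.columns:
                    if col == "model":
                        row[col] = f"family_{lab}_mean"
                    elif col == "family_label":
                        row[col] = lab
                    elif col in agg:
                        row[col] = agg[col][0]
                extra.append(row)
            table = pd.concat([table, pd.DataFrame(extra)], ignore_index=True)
        table.to_csv(path, sep="\t", index=False,
                     float_format=f"%.{float_precision}f")
    elif format == "structured":
        with open(path, "w") as fh:
            json.dump(_jsonify(table), fh, indent=1, sort_keys=False)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown report format '{format}'")


def read_report(path: str | Path):
    """Read back a ``structured`` report; DataFrames are reconstructed."""
    with open(path) as fh:
        obj = json.load(fh)

    def revive(o):
        if isinstance(o, dict):
            if o.get("__dataframe__"):
                return pd.DataFrame(o["data"], columns=o["columns"])
            return {k: revive(v) for k, v in o.items()}
        if isinstance(o, list):
            return [revive(v) for v in o]
        return o

    return revive(obj)
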