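"""Reading, writing and assembling the on-disk formats of the workflow.

Everything downstream of quantum chemistry arrives as plain text: multi-frame
XYZ files carrying one free energy per conformer in the comment line,
per-conformer electronic-property tables as CSV, reaction-outcome tables as
CSV, and the assembled reaction-by-descriptor feature matrices.  This module
owns those formats and the container types the rest of the package operates
on.

XYZ dialect
-----------
Each frame is ``N`` atoms, then a comment line ``E=<float> id=<string>``
(energy in kcal/mol; only differences are ever used), then ``N`` lines of
``El x y z`` in Å.  Atom indices are 1-based in every user-facing file and
descriptor definition, 0-based internally; the conversion happens here and in
the catalogue loader, nowhere else.

Feature provenance
------------------
Feature-matrix columns are named ``<descriptor>__<STAGE>__<agg>`` so that the
stage (TSRC / Int / TSRE / surrogate) and the aggregation statistic survive a
CSV round trip without side tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STAGE_LABELS = ("TSRC", "Int", "TSRE", "surrogate")

#: Aggregation statistics collected per descriptor over a conformer ensemble.
AGGREGATIONS = ("min", "max", "boltz", "lowE")

_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm",
    "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W",
    "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb", "Bi", "Po", "At", "Rn",
}


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


@dataclass
class Structure:
    """One stationary-point geometry (a TS, intermediate or surrogate)."""

    elements: list[str]
    coords: np.ndarray  # (N, 3) Å
    stage_label: str = "surrogate"
    id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.elements) < 1:
            raise ValueError("a structure needs at least one atom")
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError(
                f"coordinates shape {self.coords.shape} does not match "
                f"{len(self.elements)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        bad = [e for e in self.elements if e not in _ELEMENTS]
        if bad:
            raise ValueError(f"unknown element symbols: {sorted(set(bad))}")
        if self.stage_label not in STAGE_LABELS:
            raise ValueError(
                f"stage_label must be one of {STAGE_LABELS}, got {self.stage_label!r}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class ConformerEnsemble:
    """N conformers of one structure with free energies and optional properties.

    ``properties`` maps conformer id -> record; each record maps a property
    name to a scalar or a per-atom ``np.ndarray`` (see
    :func:`read_property_table`).
    """

    conformers: list[Structure]
    free_energies: np.ndarray  # kcal/mol, one per conformer
    properties: dict[str, dict[str, object]] | None = None

    def __post_init__(self) -> None:
        self.free_energies = np.asarray(self.free_energies, dtype=float)
        if len(self.conformers) == 0:
            raise ValueError("empty ensemble")
        if self.free_energies.shape != (len(self.conformers),):
            raise ValueError("one free energy per conformer required")
        if not np.all(np.isfinite(self.free_energies)):
            raise ValueError("non-finite free energies")
        ref = self.conformers[0].elements
        for c in self.conformers[1:]:
            if c.elements != ref:
                raise ValueError("conformers differ in element sequence")
        if self.properties is not None:
            ids = {c.id for c in self.conformers}
            missing = ids - set(self.properties)
            if missing:
                raise ValueError(f"property records missing for conformers: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def stage_label(self) -> str:
        return self.conformers[0].stage_label

    def subset(self, indices: Iterable[int]) -> "ConformerEnsemble":
        idx = list(indices)
        props = None
        if self.properties is not None:
            props = {self.conformers[i].id: self.properties[self.conformers[i].id] for i in idx}
        return ConformerEnsemble(
            conformers=[self.conformers[i] for i in idx],
            free_energies=self.free_energies[idx],
            properties=props,
        )


@dataclass
class ReactionRecord:
    """One experiment: a ligand applied to a reaction at some temperature."""

    reaction_id: str
    ligand_id: str = ""
    substrate_ids: tuple[str, ...] = ()
    stage_refs: Mapping[str, str] = field(default_factory=dict)
    temperature: float = 298.15  # K
    ee: float | None = None  # fraction in [-1, 1]
    ddg: float | None = None  # kcal/mol

    def __post_init__(self) -> None:
        if self.ee is None and self.ddg is None:
            raise ValueError(f"record {self.reaction_id}: need at least one of ee/ddg")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.ee is not None and not -1 <= self.ee <= 1:
            raise ValueError(f"ee must lie in [-1, 1], got {self.ee}")


_PROVENANCE_RE = re.compile(r"^(?P<name>.+)__(?P<stage>[A-Za-z]+)__(?P<agg>[A-Za-z]+)$")


def parse_column_provenance(column: str) -> dict[str, str]:
    """Split ``name__STAGE__agg`` into its provenance fields.

    Columns without the suffix convention get stage/agg ``"unknown"``.
    """
    m = _PROVENANCE_RE.match(column)
    if m and m.group("stage") in STAGE_LABELS and m.group("agg") in AGGREGATIONS:
        return {"name": m.group("name"), "stage": m.group("stage"), "agg": m.group("agg")}
    return {"name": column, "stage": "unknown", "agg": "unknown"}


class FeatureMatrix:
    """Reaction-by-descriptor matrix with per-column provenance.

    Thin wrapper over a pandas DataFrame whose index is reaction ids and whose
    column names encode provenance as ``name__STAGE__agg``.
    """

    def __init__(self, data: pd.DataFrame):
        if data.columns.duplicated().any():
            dupes = data.columns[data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate column names: {dupes}")
        if data.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        self.data = data.astype(float)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def row_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def provenance(self) -> pd.DataFrame:
        """Per-column provenance table (name, stage, agg)."""
        recs = [parse_column_provenance(c) for c in self.columns]
        return pd.DataFrame(recs, index=self.columns)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# XYZ ensembles
# ---------------------------------------------------------------------------

_COMMENT_RE = re.compile(r"E=(?P<energy>[^\s]+)(?:\s+id=(?P<id>\S+))?")


def read_xyz_ensemble(path: str | Path, stage_label: str = "surrogate") -> ConformerEnsemble:
    """Read a multi-frame XYZ file into a :class:`ConformerEnsemble`.

    Frame comment lines must carry ``E=<float>`` (kcal/mol) and may carry
    ``id=<string>``; frames without an id are numbered ``conf_<k>``.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    conformers: list[Structure] = []
    energies: list[float] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}")
        if i + 1 >= len(lines):
            raise FormatError(f"{path}:{i + 1}: truncated frame (missing comment line)")
        m = _COMMENT_RE.search(lines[i + 1])
        if not m:
            raise FormatError(f"{path}:{i + 2}: missing 'E=<float>' energy token")
        try:
            energy = float(m.group("energy"))
        except ValueError:
            raise FormatError(f"{path}:{i + 2}: non-numeric energy {m.group('energy')!r}")
        conf_id = m.group("id") or f"conf_{frame}"
        elements: list[str] = []
        coords: list[list[float]] = []
        for j in range(n):
            ln = i + 2 + j
            if ln >= len(lines) or not lines[ln].strip() or _looks_like_count(lines[ln]):
                raise FormatError(
                    f"{path}:{i + 1}: frame declares {n} atoms but lists {j}"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln + 1}: expected 'El x y z', got {lines[ln]!r}")
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise FormatError(f"{path}:{ln + 1}: non-numeric coordinate in {lines[ln]!r}")
            elements.append(parts[0])
            coords.append(xyz)
        conformers.append(
            Structure(elements, np.array(coords), stage_label=stage_label, id=conf_id)
        )
        energies.append(energy)
        i += 2 + n
        frame += 1
    if not conformers:
        raise FormatError(f"{path}: no frames found")
    return ConformerEnsemble(conformers, np.array(energies))


def _looks_like_count(line: str) -> bool:
    parts = line.split()
    return len(parts) == 1 and parts[0].isdigit()


def write_xyz_ensemble(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write an ensemble in the multi-frame XYZ dialect (coordinates %.8f)."""
    path = Path(path)
    out: list[str] = []
    for conf, energy in zip(ensemble.conformers, ensemble.free_energies):
        out.append(str(conf.n_atoms))
        out.append(f"E={energy:.10g} id={conf.id}")
        for el, (x, y, z) in zip(conf.elements, conf.coords):
            out.append(f"{el} {x:.8f} {y:.8f} {z:.8f}")
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Property tables
# ---------------------------------------------------------------------------

_ATOM_COL_RE = re.compile(r"^(?P<name>.+)\[(?P<index>\d+)\]$")


def read_property_table(path: str | Path) -> dict[str, dict[str, object]]:
    """Read a per-conformer electronic-property CSV.

    The first column is the conformer id.  Scalar columns (``eps_homo``) map
    to floats; atom-indexed columns (``hirshfeld_q[12]``, 1-based) are
    collected into per-atom arrays under the bare name (0-based internally).
    """
    df = pd.read_csv(path)
    id_col = df.columns[0]
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate conformer ids: {dupes}")
    scalar_cols: list[str] = []
    atom_cols: dict[str, list[tuple[int, str]]] = {}
    for col in df.columns[1:]:
        m = _ATOM_COL_RE.match(col)
        if m:
            atom_cols.setdefault(m.group("name"), []).append((int(m.group("index")), col))
        else:
            scalar_cols.append(col)
    for col in df.columns[1:]:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()].iloc[0]
            raise FormatError(f"{path}: non-numeric cell {bad!r} in column {col!r}")
    records: dict[str, dict[str, object]] = {}
    for i, cid in enumerate(ids):
        rec: dict[str, object] = {c: float(df[c].iloc[i]) for c in scalar_cols}
        for name, indexed in atom_cols.items():
            indexed = sorted(indexed)
            arr = np.full(max(idx for idx, _ in indexed), np.nan)
            for idx, col in indexed:
                arr[idx - 1] = df[col].iloc[i]  # 1-based on disk
            rec[name] = arr
        records[cid] = rec
    return records


def write_property_table(records: dict[str, dict[str, object]], path: str | Path) -> None:
    """Inverse of :func:`read_property_table` (deterministic column order)."""
    rows = []
    for cid in records:
        row: dict[str, float] = {"conformer_id": cid}
        for name, val in records[cid].items():
            if np.isscalar(val):
                row[name] = float(val)
            else:
                for i, v in enumerate(np.asarray(val)):
                    row[f"{name}[{i + 1}]"] = float(v)
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = ["conformer_id"] + sorted(c for c in df.columns if c != "conformer_id")
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature matrices and reaction datasets
# ---------------------------------------------------------------------------


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "reaction_id"
    df.to_csv(path, float_format="%.12g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    dupes = [h for h in set(header) if header.count(h) > 1]
    if dupes:  # pandas silently renames duplicates, so check the raw header
        raise FormatError(f"{path}: duplicate column names: {sorted(dupes)}")
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate column names: {dupes}")
    return FeatureMatrix(df)


def load_reaction_dataset(
    outcomes_path: str | Path,
    feature_matrix_path: str | Path,
    default_temperature: float = 298.15,
) -> tuple[list[ReactionRecord], FeatureMatrix, list[str]]:
    """Join an outcome table with a feature matrix on reaction id.

    The outcome CSV needs a ``reaction_id`` column and at least one of
    ``ee`` / ``ddg``; optional columns: ``ligand_id``, ``temperature`` (K).
    e.e. values with magnitude > 1 are interpreted as percent.  Missing ΔΔG‡
    is filled from e.e. at the record's temperature.

    Returns (records, features restricted to the join, dropped ids).
    """
    from .selectivity import ee_to_ddg

    outcomes = pd.read_csv(outcomes_path)
    if "reaction_id" not in outcomes.columns:
        raise FormatError(f"{outcomes_path}: missing 'reaction_id' column")
    matrix = read_feature_matrix(feature_matrix_path)
    outcomes["reaction_id"] = outcomes["reaction_id"].astype(str)
    keep = outcomes["reaction_id"].isin(matrix.row_ids)
    dropped = sorted(
        set(outcomes.loc[~keep, "reaction_id"]) | (set(matrix.row_ids) - set(outcomes["reaction_id"]))
    )
    joined = outcomes[keep]
    if joined.empty:
        raise ValueError("no overlapping reaction ids between outcomes and features")
    records: list[ReactionRecord] = []
    for _, row in joined.iterrows():
        temperature = row.get("temperature", np.nan)
        temperature = default_temperature if pd.isna(temperature) else float(temperature)
        ee = row.get("ee")
        ddg = row.get("ddg")
        ee = None if pd.isna(ee) else float(ee)
        ddg = None if pd.isna(ddg) else float(ddg)
        if ee is not None and abs(ee) > 1:  # percent on disk
            ee = ee / 100.0
        if ddg is None and ee is not None:
            ddg = ee_to_ddg(ee, temperature)
        records.append(
            ReactionRecord(
                reaction_id=str(row["reaction_id"]),
                ligand_id=str(row.get("ligand_id", "") or ""),
                temperature=temperature,
                ee=ee,
                ddg=ddg,
            )
        )
    # restrict + order the matrix rows to the record order
    sub = matrix.data.loc[[r.reaction_id for r in records]]
    return records, FeatureMatrix(sub), dropped
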