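"""File formats: rate tables, trace files, multi-model PDB, YAML config.

Rate tables are delimited text with the header::

    complex_id,ncbd_variant,cid_variant,probe,condition,
    kon,kon_se,koff,koff_se,koff_source,status[,...]

Unknown columns are preserved on round-trip. Rows whose rate cells read
"Too unstable complex" (as printed in the source tables) map to
``status=too_unstable`` with null rates.

Traces are two-column delimited text (``time_s,signal``), one file per
trace, with a JSON sidecar carrying concentrations and condition tags.
Structure ensembles use standard multi-model PDB (Å on disk, nm in
memory).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensemble import StructureEnsemble
from .kinetics import Trace, TraceSet
from .phi import RateRecord

__all__ = [
    "read_rate_table",
    "write_rate_table",
    "records_from_frame",
    "frame_from_records",
    "load_packaged_table",
    "read_trace",
    "write_trace",
    "read_trace_dir",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "load_config",
    "save_config",
]

_NUMERIC_COLS = ("kon", "kon_se", "koff", "koff_se")
_UNSTABLE_TEXT = "too unstable complex"


def _clean_cell(v):
    if isinstance(v, str) and v.strip().lower() in (_UNSTABLE_TEXT, "-", ""):
        return None
    return v


def read_rate_table(path: str | Path) -> pd.DataFrame:
    """Read a mutant rate-constant table, normalizing status markers."""
    df = pd.read_csv(path, dtype={"condition": str}, keep_default_na=True,
                     float_precision="round_trip")
    if "status" not in df.columns:
        df["status"] = "ok"
    for col in _NUMERIC_COLS:
        if col not in df.columns:
            continue
        cleaned = df[col].map(_clean_cell)
        unstable_text = df[col].astype(str).str.strip().str.lower() == _UNSTABLE_TEXT
        df.loc[unstable_text, "status"] = "too_unstable"
        try:
            df[col] = pd.to_numeric(cleaned)
        except (ValueError, TypeError):
            for line, v in enumerate(cleaned, start=2):  # 1-based + header
                if v is None:
                    continue
                try:
                    float(v)
                except (ValueError, TypeError):
                    raise ValueError(
                        f"{path}, line {line}: malformed numeric value "
                        f"{v!r} in column {col!r}"
                    ) from None
    df["status"] = df["status"].fillna("ok").replace("", "ok")
    if "condition" in df.columns:
        df["condition"] = df["condition"].fillna("")
    return df


def write_rate_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def records_from_frame(df: pd.DataFrame) -> list[RateRecord]:
    known = {
        "complex_id", "ncbd_variant", "cid_variant", "probe", "condition",
        "kon", "kon_se", "koff", "koff_se", "koff_source", "status", "group",
    }
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in known:
            if col not in df.columns:
                continue
            v = row[col]
            if pd.isna(v):
                v = None if col in _NUMERIC_COLS else ""
            kwargs[col] = v
        if kwargs.get("status") in (None, ""):
            kwargs["status"] = "ok"
        if not kwargs.get("koff_source"):
            kwargs["koff_source"] = "binding_fit"
        records.append(RateRecord(**kwargs))
    return records


def frame_from_records(records: list[RateRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def load_packaged_table(name: str) -> pd.DataFrame:
    """Load one of the packaged mutant tables: 'table1'|'table2'|'table3'."""
    ref = resources.files("phimap.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as p:
        return read_rate_table(p)


# ---------------------------------------------------------------------------
# traces


def write_trace(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "signal": trace.signal}).to_csv(
        path, index=False
    )
    sidecar = {
        "concentrations": trace.concentrations,
        "condition": trace.condition,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Trace(
        time=df["time_s"].to_numpy(),
        signal=df["signal"].to_numpy(),
        concentrations=meta.get("concentrations", {}),
        condition=meta.get("condition", ""),
    )


def read_trace_dir(directory: str | Path) -> TraceSet:
    directory = Path(directory)
    traces = [read_trace(p) for p in sorted(directory.glob("*.csv"))]
    if not traces:
        raise ValueError(f"no trace files (*.csv) found in {directory}")
    return TraceSet(traces=traces, label=str(directory))


# ---------------------------------------------------------------------------
# structure ensembles (multi-model PDB, Å on disk, nm in memory)


def read_pdb_ensemble(path: str | Path) -> StructureEnsemble:
    from biotite.structure.io.pdb import PDBFile

    pdbf = PDBFile.read(str(path))
    try:
        stack = pdbf.get_structure(model=None)
    except Exception as exc:
        raise ValueError(
            f"{path}: could not read a consistent multi-model ensemble "
            f"(mixed topology across models?): {exc}"
        ) from exc
    coords = np.atleast_3d(stack.coord)
    if coords.ndim == 2:
        coords = coords[None]
    elements = [
        el if el else (nm[0] if nm else "C")
        for el, nm in zip(stack.element, stack.atom_name)
    ]
    atoms = pd.DataFrame(
        {
            "chain": stack.chain_id,
            "resid": stack.res_id,
            "resname": stack.res_name,
            "name": stack.atom_name,
            "element": elements,
        }
    )
    return StructureEnsemble(atoms=atoms, coords=coords / 10.0)


def write_pdb_ensemble(ensemble: StructureEnsemble, path: str | Path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_atoms = ensemble.n_atoms
    template = struc.AtomArray(n_atoms)
    template.chain_id = ensemble.atoms["chain"].astype(str).to_numpy().astype("U4")
    template.res_id = ensemble.atoms["resid"].astype(int).to_numpy()
    template.res_name = ensemble.atoms["resname"].astype(str).to_numpy().astype("U5")
    template.atom_name = ensemble.atoms["name"].astype(str).to_numpy().astype("U6")
    template.element = ensemble.atoms["element"].astype(str).to_numpy().astype("U2")
    stack = struc.stack(
        [template] * ensemble.n_models
    )
    stack.coord = ensemble.coords * 10.0
    pdbf = PDBFile()
    pdbf.set_structure(stack)
    pdbf.write(str(path))


# ---------------------------------------------------------------------------
# YAML configuration


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
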