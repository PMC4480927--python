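"""File formats: long-format TSV tensors, per-timepoint matrix directories,
tricluster JSON/TSV, GMT annotation files and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ExpressionTensor, Tricluster, TriclusterSet
from .exceptions import TriclusterError
from .metrics import AnnotationCollection

__all__ = [
    "read_tensor",
    "write_tensor",
    "write_triclusters",
    "read_triclusters",
    "read_gmt",
    "write_manifest",
    "file_digest",
]

_LONG_COLUMNS = ("gene", "sample", "timepoint", "value")


def read_tensor(path, format: str = "long_tsv") -> ExpressionTensor:
    """Read a tensor from ``long_tsv`` (gene/sample/timepoint/value rows)
    or ``matrix_dir`` (one genes x samples matrix per time point).

    Absent (gene, sample, timepoint) triples become unobserved cells;
    axis orders follow first appearance (long_tsv) or file order
    (matrix_dir, lexicographic unless a ``timepoints.txt`` ordering file
    is present).
    """
    if format == "long_tsv":
        return _read_long_tsv(Path(path))
    if format == "matrix_dir":
        return _read_matrix_dir(Path(path))
    raise TriclusterError(f"unknown tensor format {format!r}")


def _read_long_tsv(path: Path) -> ExpressionTensor:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TriclusterError(f"{path}: missing required column(s) {missing_cols}")
    try:
        # numpy's strtod-based parser round-trips float64 exactly (the
        # pandas fast parser can be off by one ulp)
        parsed = df["value"].to_numpy(dtype=float)
    except (TypeError, ValueError):
        for pos, raw in enumerate(df["value"]):
            try:
                float(raw)
            except (TypeError, ValueError):
                raise TriclusterError(
                    f"{path}: non-numeric value on line {pos + 2}"
                ) from None
        raise
    values = pd.Series(parsed, index=df.index)
    dup = df.duplicated(subset=["gene", "sample", "timepoint"])
    if dup.any():
        row = df[dup].iloc[0]
        raise TriclusterError(
            f"{path}: duplicate triple ({row['gene']}, {row['sample']}, {row['timepoint']})"
        )
    genes = pd.unique(df["gene"])
    samples = pd.unique(df["sample"])
    times = pd.unique(df["timepoint"])
    gi = pd.Series(range(len(genes)), index=genes)
    si = pd.Series(range(len(samples)), index=samples)
    ti = pd.Series(range(len(times)), index=times)
    arr = np.full((len(genes), len(samples), len(times)), np.nan)
    arr[gi[df["gene"]].to_numpy(), si[df["sample"]].to_numpy(), ti[df["timepoint"]].to_numpy()] = (
        values.to_numpy()
    )
    mask = ~np.isnan(arr)
    # NaN values in the file itself also mean unobserved
    return ExpressionTensor(
        values=np.where(mask, arr, 0.0),
        gene_ids=tuple(genes),
        sample_ids=tuple(samples),
        time_ids=tuple(times),
        mask=mask,
    )


def _read_matrix_dir(path: Path) -> ExpressionTensor:
    order_file = path / "timepoints.txt"
    if order_file.exists():
        names = [ln.strip() for ln in order_file.read_text().splitlines() if ln.strip()]
        files = [path / n for n in names]
    else:
        files = sorted(p for p in path.glob("*.tsv"))
    if not files:
        raise TriclusterError(f"{path}: no per-timepoint matrices found")
    frames = []
    for f in files:
        m = pd.read_csv(f, sep="\t", index_col=0, float_precision="round_trip")
        frames.append(m)
    genes, samples = list(frames[0].index), list(frames[0].columns)
    for f, m in zip(files, frames):
        if list(m.index) != genes or list(m.columns) != samples:
            raise TriclusterError(f"{f}: gene/sample labels differ between time points")
    arr = np.stack([m.to_numpy(dtype=float) for m in frames], axis=2)
    mask = ~np.isnan(arr)
    return ExpressionTensor(
        values=np.where(mask, arr, 0.0),
        gene_ids=tuple(map(str, genes)),
        sample_ids=tuple(map(str, samples)),
        time_ids=tuple(f.stem for f in files),
        mask=mask,
    )


def write_tensor(tensor: ExpressionTensor, path) -> None:
    """Write a tensor as long-format TSV (unobserved cells are omitted)."""
    gi, si, ti = np.nonzero(tensor.mask)
    df = pd.DataFrame(
        {
            "gene": [tensor.gene_ids[i] for i in gi],
            "sample": [tensor.sample_ids[j] for j in si],
            "timepoint": [tensor.time_ids[k] for k in ti],
            "value": tensor.values[gi, si, ti],
        }
    )
    # %.17g round-trips any float64 exactly
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_triclusters(tset: TriclusterSet, json_path, tsv_path=None) -> None:
    """Write a tricluster set as JSON plus a flat (id, axis, label) TSV."""
    json_path = Path(json_path)
    if tsv_path is None:
        tsv_path = json_path.with_suffix(".tsv")
    entries = []
    for i, tric in enumerate(tset):
        genes, samples, times = tset.label_sets(i)
        entry = {
            "id": i,
            "genes": sorted(genes),
            "samples": sorted(samples),
            "times": sorted(times),
            "msr": tric.msr,
            "volume": tric.volume,
        }
        if tset.objectives is not None:
            o = tset.objectives[i]
            entry["objectives"] = {"f1": o.f1, "f2": o.f2, "f3": o.f3}
        entries.append(entry)
    doc = {
        "format": "emoatrimax-triclusters",
        "version": 1,
        "axes": {
            "genes": list(tset.gene_ids),
            "samples": list(tset.sample_ids),
            "times": list(tset.time_ids),
        },
        "triclusters": entries,
        "provenance": _jsonable(dict(tset.provenance)),
        "trace": [
            {
                "generation": t.generation,
                "min_sum": t.min_sum,
                "front_sizes": list(t.front_sizes),
                "archive_size": t.archive_size,
            }
            for t in tset.traces
        ],
    }
    json_path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    rows = []
    for i, tric in enumerate(tset):
        genes, samples, times = tset.label_sets(i)
        rows.extend((i, "gene", g) for g in sorted(genes))
        rows.extend((i, "sample", s) for s in sorted(samples))
        rows.extend((i, "time", t) for t in sorted(times))
    pd.DataFrame(rows, columns=["tricluster_id", "axis", "label"]).to_csv(
        tsv_path, sep="\t", index=False
    )


def read_triclusters(json_path, tensor: ExpressionTensor | None = None) -> TriclusterSet:
    """Read a tricluster set; with a tensor, indices and MSR are recomputed
    against it, otherwise the stored values are trusted."""
    doc = json.loads(Path(json_path).read_text())
    if doc.get("format") != "emoatrimax-triclusters":
        raise TriclusterError(f"{json_path}: not a tricluster file")
    axes = doc["axes"]
    if tensor is not None:
        gene_pos = {g: i for i, g in enumerate(tensor.gene_ids)}
        sample_pos = {s: i for i, s in enumerate(tensor.sample_ids)}
        time_pos = {t: i for i, t in enumerate(tensor.time_ids)}
        gene_ids, sample_ids, time_ids = tensor.gene_ids, tensor.sample_ids, tensor.time_ids
    else:
        gene_pos = {g: i for i, g in enumerate(axes["genes"])}
        sample_pos = {s: i for i, s in enumerate(axes["samples"])}
        time_pos = {t: i for i, t in enumerate(axes["times"])}
        gene_ids, sample_ids, time_ids = axes["genes"], axes["samples"], axes["times"]
    trics = []
    for entry in doc["triclusters"]:
        I = sorted(gene_pos[g] for g in entry["genes"])
        J = sorted(sample_pos[s] for s in entry["samples"])
        K = sorted(time_pos[t] for t in entry["times"])
        if tensor is not None:
            trics.append(Tricluster.from_indices(tensor, I, J, K))
        else:
            trics.append(
                Tricluster(
                    tuple(I), tuple(J), tuple(K), float(entry["msr"]), int(entry["volume"])
                )
            )
    return TriclusterSet(
        triclusters=tuple(trics),
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(sample_ids),
        time_ids=tuple(time_ids),
        provenance=doc.get("provenance", {}),
    )


def read_gmt(path, universe=None) -> AnnotationCollection:
    """Read GMT (set name, description, genes...); the universe defaults to
    the union of all sets."""
    sets = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise TriclusterError(f"{path}: GMT lines need name, description and genes")
        sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return AnnotationCollection(sets=sets, universe=frozenset(universe))


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(manifest: dict, path) -> None:
    """YAML run manifest; contains everything needed to re-run bit-identically."""
    Path(path).write_text(yaml.safe_dump(_jsonable(manifest), sort_keys=True))
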