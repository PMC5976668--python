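"""File formats: tab-delimited expression matrices, CSV tables, JSON results.

The expression-matrix dialect is the common series-matrix layout: genes as
rows, a header row of sample ids, the first column holding gene ids, tab
delimited, decimal points, no thousands separators.  Leading ``#`` lines
are a provenance block and are skipped on read; gzip-compressed files
(``.gz`` suffix) are read and written transparently.
"""
from __future__ import annotations

import gzip
import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ParseError

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "read_subjects",
    "write_signature_json",
    "write_sampler_json",
    "provenance_block",
    "sha256_of",
]


def _opener(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def provenance_block(seed=None, config_hash: str | None = None) -> dict:
    block = {"tool": "fatiguesig", "version": __version__}
    if seed is not None:
        block["seed"] = int(seed)
    if config_hash is not None:
        block["config_hash"] = config_hash
    return block


def _provenance_lines(seed=None, config_hash=None) -> list[str]:
    return [f"# {k}: {v}" for k, v in provenance_block(seed, config_hash).items()]


def read_expression_matrix(path) -> pd.DataFrame:
    """Parse the tab-delimited matrix dialect with line-numbered errors.

    Rejects ragged rows, duplicate gene ids, and non-numeric cells, naming
    the offending line.  Round-trips with :func:`write_expression_matrix`
    to 12 significant digits.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    header: list[str] | None = None
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    seen: dict[str, int] = {}
    with _opener(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                if len(header) == 0:
                    raise ParseError(f"{path}:{lineno}: header has no sample ids")
                if len(set(header)) != len(header):
                    raise ParseError(f"{path}:{lineno}: duplicate sample ids in header")
                continue
            if len(fields) != len(header) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header) + 1} fields, got {len(fields)}"
                )
            gid = fields[0]
            if gid in seen:
                raise ParseError(
                    f"{path}:{lineno}: duplicate gene id '{gid}' (first at line {seen[gid]})"
                )
            seen[gid] = lineno
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from exc
            gene_ids.append(gid)
    if header is None:
        raise ParseError(f"{path}: empty file")
    return pd.DataFrame(
        rows, index=pd.Index(gene_ids, name="gene_id"), columns=pd.Index(header, name="sample_id")
    )


def write_expression_matrix(matrix: pd.DataFrame, path, *, seed=None, config_hash=None) -> None:
    path = Path(path)
    with _opener(path, "w") as fh:
        for line in _provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        fh.write("gene_id\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for gid, row in zip(matrix.index, matrix.to_numpy()):
            fh.write(str(gid) + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def write_csv(frame: pd.DataFrame, path, *, seed=None, config_hash=None, index=True) -> None:
    """CSV with a leading provenance comment block."""
    with _opener(path, "w") as fh:
        for line in _provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        frame.to_csv(fh, index=index)


def read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_labels(labels: pd.Series, path, *, seed=None) -> None:
    write_csv(labels.rename("class").rename_axis("sample_id").to_frame(), path, seed=seed)


def read_labels(path) -> pd.Series:
    frame = read_csv(path)
    if not {"sample_id", "class"}.issubset(frame.columns):
        raise ParseError(f"{path}: labels file needs 'sample_id' and 'class' columns")
    return frame.set_index("sample_id")["class"]


def read_subjects(path) -> pd.DataFrame:
    frame = read_csv(path)
    required = {"subject_id", "factf_baseline", "factf_1yr"}
    if not required.issubset(frame.columns):
        raise ParseError(f"{path}: subjects file needs columns {sorted(required)}")
    return frame


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset, pd.Index)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_json(payload: dict, path, *, seed=None, config_hash=None) -> None:
    payload = dict(payload)
    payload["provenance"] = provenance_block(seed, config_hash)
    with _opener(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_signature_json(signature, path, *, params=None, seed=None) -> None:
    write_json(
        {
            "genes": list(signature.gene_ids),
            "loocv_accuracy": signature.loocv_accuracy,
            "accuracy_curve": [[k, a] for k, a in signature.accuracy_curve],
            "params": params or {},
        },
        path,
        seed=seed,
    )


def write_sampler_json(result, path, *, seed=None) -> None:
    write_json(
        {
            "networks": [[list(genes), acc] for genes, acc in result.networks],
            "n_retained": result.n_retained,
            "n_draws": result.n_draws,
            "posterior_frequency": result.posterior_frequency,
        },
        path,
        seed=seed,
    )


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
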