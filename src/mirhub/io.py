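"""Readers and writers for the pipeline's tab-separated table formats.

All tables round-trip: whatever a writer emits, the matching reader
reconstructs exactly.  Count matrices are feature x sample with the feature
id in the first column and sample ids in the header row; edge lists are
2-column (predictions) or 4-column (inferred networks, stratum recorded in
a header comment); gene sets use the standard GMT layout.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_clinical
from .netinfer import InteractionNetwork
from .qpcr import CtMatrix
from .signature import LogisticSignature

_INTERCEPT_KEY = "(intercept)"


def _check_nonempty(path: Path) -> None:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")


def read_count_matrix(path, scale: str = "raw") -> ExpressionMatrix:
    """Read a feature x sample matrix, validating ids and count integrality."""
    _check_nonempty(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        rows, index = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} columns, found {len(parts)}"
                )
            index.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from err
    if not rows:
        raise ValueError(f"{path}: no data rows")
    dup = pd.Index(index)
    if dup.has_duplicates:
        names = dup[dup.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {names}")
    values = pd.DataFrame(rows, index=index, columns=header[1:])
    if scale == "raw":
        arr = values.to_numpy()
        if (arr < 0).any():
            bad = int(np.argwhere((arr < 0).any(axis=1))[0][0])
            raise ValueError(f"{path}: negative count in row {index[bad]!r}")
        values = values.astype(np.int64)
    return ExpressionMatrix(values, scale=scale)


def write_count_matrix(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="feature_id")


def read_clinical_table(path) -> pd.DataFrame:
    _check_nonempty(path)
    clinical = pd.read_csv(path, sep="\t", index_col=0)
    return validate_clinical(clinical)


def write_clinical_table(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample_id")


def read_prediction_edges(path) -> set[tuple[str, str]]:
    """Two-column miRNA -> gene predicted-target list."""
    _check_nonempty(path)
    edges = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            edges.add((parts[0], parts[1]))
    return edges


def write_prediction_edges(edges: set[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for m, g in sorted(edges):
            fh.write(f"{m}\t{g}\n")


def read_network(path) -> InteractionNetwork:
    """Four-column (regulator, target, mi, support) list with stratum comment."""
    _check_nonempty(path)
    stratum = "all"
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "stratum=" in line:
                    stratum = line.split("stratum=")[1].strip()
                continue
            if line.strip().startswith("regulator"):
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append((parts[0], parts[1], float(parts[2]), float(parts[3])))
    edges = pd.DataFrame(rows, columns=["regulator", "target", "mi", "support"])
    return InteractionNetwork(edges=edges, stratum=stratum)


def write_network(net: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stratum={net.stratum}\n")
        fh.write("regulator\ttarget\tmi\tsupport\n")
        for row in net.edges.itertuples(index=False):
            fh.write(f"{row.regulator}\t{row.target}\t{row.mi!r}\t{row.support!r}\n")


def read_gmt(path) -> dict[str, set[str]]:
    _check_nonempty(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need name, description, members")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_feature_list(path) -> list[str]:
    """One feature id per line (panel files, selection lists)."""
    _check_nonempty(path)
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_feature_list(features, path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f}\n")


def read_cluster_assignments(path) -> pd.Series:
    _check_nonempty(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("cluster")


def write_cluster_assignments(clusters: pd.Series, path) -> None:
    clusters.rename("cluster").to_csv(path, sep="\t", index_label="sample_id")


def read_de_table(path) -> pd.DataFrame:
    _check_nonempty(path)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="feature_id")


def read_ct_matrix(path) -> CtMatrix:
    _check_nonempty(path)
    with open(path) as fh:
        normalized = fh.readline().startswith("#normalized")
    values = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], skiprows=1 if normalized else 0
    )
    values.index.name = None
    values.columns.name = None
    return CtMatrix(values=values, normalized=normalized)


def write_ct_matrix(ct: CtMatrix, path) -> None:
    with open(path, "w") as fh:
        if ct.normalized:
            fh.write("#normalized\n")
        ct.values.to_csv(fh, sep="\t", index_label="feature_id", na_rep="NA")


def read_signature(path) -> LogisticSignature:
    _check_nonempty(path)
    feats, coefs = [], []
    intercept = 0.0
    lam = 0.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#lambda"):
                lam = float(line.split("\t")[1])
                continue
            if line.startswith("#") or line.startswith("feature"):
                continue
            name, val = line.rstrip("\n").split("\t")
            if name == _INTERCEPT_KEY:
                intercept = float(val)
            else:
                feats.append(name)
                coefs.append(float(val))
    return LogisticSignature(feats, coefs, intercept, lam)


def write_signature(sig: LogisticSignature, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#lambda\t{sig.lambda_!r}\n")
        fh.write("feature\tcoefficient\n")
        for f, c in zip(sig.feature_ids, sig.coefficients):
            fh.write(f"{f}\t{c!r}\n")
        fh.write(f"{_INTERCEPT_KEY}\t{sig.intercept!r}\n")


def read_risk_weights(path) -> tuple[list[str], list[float]]:
    """User-supplied gene risk weights: two-column (gene, weight)."""
    _check_nonempty(path)
    genes, weights = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            g, w = line.rstrip("\n").split("\t")
            genes.append(g)
            weights.append(float(w))
    return genes, weights


def write_risk_weights(genes, weights, path) -> None:
    with open(path, "w") as fh:
        for g, w in zip(genes, weights):
            fh.write(f"{g}\t{w!r}\n")
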