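"""Plain-text readers and writers for the pipeline's artifacts.

Everything is TSV or JSON: a ratio matrix travels as a genes x samples TSV
plus a sample-metadata sidecar (sample id, time_h, dye, replicate); raw
intensities as one TSV per array (spot_id, print_tip, cy3, cy5) with an
array-metadata table; rankings and edge lists as TSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import RatioMatrix, TwoColorArraySet
from .network import GgmNetwork
from .synthetic import SyntheticTruth

REQUIRED_SAMPLE_COLUMNS = ("time_h", "dye")


def write_ratio_matrix(matrix: RatioMatrix, path, meta_path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    matrix.samples.to_csv(meta_path, sep="\t", index_label="sample")


def read_ratio_matrix(path, meta_path) -> RatioMatrix:
    """Read a ratio matrix TSV + metadata sidecar into a typed container.

    Validates the factor schema: the metadata must carry ``time_h`` and
    ``dye`` columns and describe exactly the matrix's sample columns.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    missing = set(REQUIRED_SAMPLE_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(
            f"sample metadata is missing column(s): {sorted(missing)}"
        )
    if len(meta) != values.shape[1]:
        raise ValueError(
            f"metadata describes {len(meta)} samples but the matrix has "
            f"{values.shape[1]} columns"
        )
    if set(meta.index) != set(values.columns):
        raise ValueError("metadata sample ids do not match matrix columns")
    return RatioMatrix(values[meta.index.tolist()], meta)


def write_intensity_dataset(arrays: TwoColorArraySet, out_dir) -> None:
    """One per-array spot TSV plus an array-metadata TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays.arrays.to_csv(out / "arrays.tsv", sep="\t", index_label="array")
    for arr in arrays.arrays.index:
        df = pd.DataFrame({
            "print_tip": arrays.spots["print_tip"],
            "cy3": arrays.cy3[arr],
            "cy5": arrays.cy5[arr],
            "present": arrays.mask[arr].astype(int),
        })
        df.to_csv(out / f"array_{arr}.tsv", sep="\t", index_label="spot_id")


def read_intensity_dataset(in_dir) -> TwoColorArraySet:
    src = Path(in_dir)
    meta = pd.read_csv(src / "arrays.tsv", sep="\t", index_col=0)
    cy3, cy5, mask, spots = {}, {}, {}, None
    for arr in meta.index:
        df = pd.read_csv(src / f"array_{arr}.tsv", sep="\t", index_col=0)
        if spots is None:
            spots = df[["print_tip"]].copy()
        elif not spots.index.equals(df.index):
            raise ValueError(f"array {arr} has a different spot universe")
        cy3[arr], cy5[arr] = df["cy3"], df["cy5"]
        mask[arr] = df["present"].astype(bool)
    return TwoColorArraySet(
        spots=spots,
        arrays=meta,
        cy3=pd.DataFrame(cy3),
        cy5=pd.DataFrame(cy5),
        mask=pd.DataFrame(mask),
    )


def write_ma_plot_data(ma_pre, ma_post, path) -> None:
    """Long-format per-spot MA data before/after normalization, for
    per-print-tip MA plots: array, spot, print_tip, A, M_raw, M_norm."""
    rows = []
    tips = ma_pre.spots["print_tip"]
    for arr in ma_pre.arrays.index:
        df = pd.DataFrame({
            "array": arr,
            "spot_id": ma_pre.m.index,
            "print_tip": tips.to_numpy(),
            "A": ma_pre.a[arr].to_numpy(),
            "M_raw": ma_pre.m[arr].to_numpy(),
            "M_norm": ma_post.m[arr].to_numpy(),
        })
        rows.append(df[ma_pre.mask[arr].to_numpy()])
    pd.concat(rows).to_csv(path, sep="\t", index=False)


def write_generalization_curve(curve, path) -> None:
    """Export the overfitting diagnostic as TSV (size, train_err, test_err)."""
    pd.DataFrame({
        "size": curve.sizes,
        "train_err": curve.train_error,
        "test_err": curve.test_error,
    }).to_csv(path, sep="\t", index=False)


def write_ranked_list(ranking: pd.DataFrame, path) -> None:
    ranking.to_csv(path, sep="\t", index_label="gene")


def write_network(net: GgmNetwork, edges_path, graphml_path=None) -> None:
    net.edges.to_csv(edges_path, sep="\t", index=False)
    if graphml_path is not None:
        import networkx as nx

        nx.write_graphml(net.to_networkx(), graphml_path)


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "de_genes": truth.de_genes,
        "interaction_genes": truth.interaction_genes,
        "network_genes": truth.network_genes,
        "edge_list": [list(e) for e in truth.edge_list],
        "true_means": {
            g: [float(v) for v in row]
            for g, row in truth.true_means.iterrows()
        },
        "time_points_h": [float(t) for t in truth.true_means.columns],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=1, default=_default))
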