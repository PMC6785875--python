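"""Reading and writing the pipeline's on-disk artifacts.

All tabular artifacts are plain TSV; trees are newick; configuration,
ground-truth sidecars and result summaries are JSON. Feature tables are
accepted features-as-rows (the convention of most profiler output) or
samples-as-rows, and always held samples x features in memory. Numeric
output is serialized at full precision (repr round-trip).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .containers import METADATA_COLUMNS, FeatureTable, SurvivalData

FEATURES_AS_ROWS = "features-as-rows"
SAMPLES_AS_ROWS = "samples-as-rows"


def _parse_tsv_matrix(path) -> tuple[list[str], list[str], np.ndarray]:
    """Strictly parse a TSV matrix, naming the offending line on error."""
    path = Path(path)
    lines = path.read_text().rstrip("\n").split("\n")
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header and at least one data row")
    header = lines[0].split("\t")
    col_ids = header[1:]
    n_cols = len(header)
    row_ids, data = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise ValueError(
                f"{path}: line {lineno} has {len(parts)} fields, expected {n_cols}")
        row_ids.append(parts[0])
        row = []
        for j, cell in enumerate(parts[1:], start=1):
            if cell == "":
                raise ValueError(f"{path}: line {lineno} has a missing value "
                                 f"(column {header[j]!r})")
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno} has non-numeric value {cell!r} "
                    f"(column {header[j]!r})") from None
        data.append(row)
    for name, ids in (("row", row_ids), ("column", col_ids)):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        if dups:
            raise ValueError(f"{path}: duplicate {name} identifiers: {sorted(set(dups))}")
    return row_ids, col_ids, np.array(data, dtype=float)


def read_feature_table(path, orientation: str = FEATURES_AS_ROWS,
                       level: str = "species",
                       taxonomy_path=None) -> FeatureTable:
    """Read a TSV feature table; optionally attach a feature->taxonomy map."""
    if orientation not in (FEATURES_AS_ROWS, SAMPLES_AS_ROWS):
        raise ValueError(f"unknown orientation hint {orientation!r}")
    row_ids, col_ids, data = _parse_tsv_matrix(path)
    if orientation == FEATURES_AS_ROWS:
        values = pd.DataFrame(data.T, index=col_ids, columns=row_ids)
    else:
        values = pd.DataFrame(data, index=row_ids, columns=col_ids)
    meta = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        meta = tax[["taxonomy"]]
    return FeatureTable(values, level=level, feature_meta=meta)


def write_feature_table(table: FeatureTable, path,
                        orientation: str = FEATURES_AS_ROWS) -> None:
    df = table.values.T if orientation == FEATURES_AS_ROWS else table.values
    label = "feature_id" if orientation == FEATURES_AS_ROWS else "sample_id"
    df.to_csv(path, sep="\t", index_label=label)


def write_taxonomy(table: FeatureTable, path) -> None:
    if table.feature_meta is None:
        raise ValueError("feature table carries no taxonomy metadata")
    table.feature_meta.to_csv(path, sep="\t", index_label="feature_id")


def read_tree(path) -> TreeNode:
    """Read a newick tree; require unique labeled leaves and nonnegative
    branch lengths on every non-root node."""
    tree = TreeNode.read(str(path))
    names = []
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            if node.name is None or node.name == "":
                raise ValueError(f"{path}: tree has an unlabeled leaf")
            names.append(node.name)
        if node.length is None:
            raise ValueError(f"{path}: tree node "
                             f"{node.name or '<internal>'} is missing a branch length")
        if node.length < 0:
            raise ValueError(f"{path}: negative branch length on "
                             f"{node.name or '<internal>'}")
    if len(names) != len(set(names)):
        raise ValueError(f"{path}: duplicate leaf labels")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path))


def read_metadata(path) -> SurvivalData:
    """Read the clinical metadata TSV into :class:`SurvivalData`."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype={"met_sites": str})
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing required columns: {missing}")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate patient ids: {dups}")
    return SurvivalData(frame)


def write_metadata(survival: SurvivalData, path) -> None:
    survival.frame.to_csv(path, sep="\t", index_label="patient_id")


def read_distance_matrix(path) -> DistanceMatrix:
    row_ids, col_ids, data = _parse_tsv_matrix(path)
    if row_ids != col_ids:
        raise ValueError(f"{path}: distance matrix row/column ids differ")
    return DistanceMatrix(data, ids=row_ids)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"cannot serialize {type(o)}")


# ---------------------------------------------------------------------------
# synthetic bundle on disk

def write_bundle(bundle, outdir) -> dict[str, str]:
    """Write a synthetic cohort in the formats the ingestion layer reads."""
    from .synthdata import SyntheticBundle  # noqa: F401 (type only)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table_16s": outdir / "table_16s.tsv",
        "taxonomy_16s": outdir / "taxonomy_16s.tsv",
        "table_shotgun": outdir / "table_shotgun.tsv",
        "taxonomy_shotgun": outdir / "taxonomy_shotgun.tsv",
        "tree": outdir / "tree_16s.nwk",
        "metadata": outdir / "metadata.tsv",
        "mgx_total": outdir / "pathways_mgx.tsv",
        "mgx_stratified": outdir / "pathways_mgx_stratified.tsv",
        "mtx_total": outdir / "pathways_mtx.tsv",
        "mtx_stratified": outdir / "pathways_mtx_stratified.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_feature_table(bundle.table_16s, paths["table_16s"])
    write_taxonomy(bundle.table_16s, paths["taxonomy_16s"])
    write_feature_table(bundle.table_shotgun, paths["table_shotgun"])
    write_taxonomy(bundle.table_shotgun, paths["taxonomy_shotgun"])
    write_tree(bundle.tree, paths["tree"])
    write_metadata(bundle.survival, paths["metadata"])
    for key, table in (("mgx", bundle.mgx), ("mtx", bundle.mtx)):
        table.total.T.to_csv(paths[f"{key}_total"], sep="\t", index_label="pathway")
        strat = table.stratified.T.copy()
        strat.index = [f"{pw}|{sp}" for pw, sp in strat.index]
        strat.to_csv(paths[f"{key}_stratified"], sep="\t", index_label="pathway|species")
    truth = bundle.truth
    write_json({
        "true_log_hr": truth.true_log_hr.to_dict(),
        "true_cluster_label": truth.true_cluster_label.to_dict(),
        "contribution_weights": (None if truth.contribution_weights is None
                                 else truth.contribution_weights.to_dict()),
        "shared_species": truth.shared_species,
        "sotu_to_species": truth.sotu_to_species,
        "seed": bundle.config.seed,
    }, paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}


def read_stratified_table(total_path, stratified_path):
    """Read HUMAnN-style total + 'pathway|species' stratified TSVs."""
    from .containers import StratifiedFunctionTable

    total = pd.read_csv(total_path, sep="\t", index_col=0).T
    strat = pd.read_csv(stratified_path, sep="\t", index_col=0).T
    strat.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split("|", 1)) for c in strat.columns],
        names=["pathway", "species"])
    return StratifiedFunctionTable(total=total, stratified=strat)
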