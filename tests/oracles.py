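"""Independent oracles used by the test suite.

These re-derive query results directly from the raw CSV files with
pandas, applying the documented evaluation steps one by one — an
implementation deliberately separate from the graph-based engine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def load_frames(data_path, label_path):
    df = pd.read_csv(data_path, skiprows=[1, 2], dtype={
        "geneID": str, "cellID": str, "imageID": str},
        float_precision="round_trip")
    labels = pd.read_csv(label_path, dtype={"geneID": str})
    return df, labels


def genes_with_label(labels: pd.DataFrame, name: str) -> set[str]:
    return set(labels.loc[labels[name] == 1, "geneID"])


_AGG = {"mean": np.mean, "median": np.median, "count": len,
        "min": np.min, "max": np.max}


def oracle_aggregate(df: pd.DataFrame, feature: str, method: str):
    """Brute-force per-gene aggregation over non-missing values."""
    out = {}
    for gene, sub in df.groupby("geneID"):
        values = sub[feature].dropna().to_numpy()
        if values.size:
            out[(gene,)] = float(_AGG[method](values))
    return out


def oracle_run_query(df: pd.DataFrame, labels: pd.DataFrame, state):
    """Sequential re-implementation of query evaluation on the raw table.

    Returns (records, errored) where records is a sorted list of
    (entity_key, x, y) and errored is True when a log10 transform is
    undefined for the surviving data.
    """
    work = df.copy()

    # step 1: descriptive-level (cell) filters on the raw rows
    for clause in state.filters:
        if clause.target_kind != "Cell":
            continue
        if clause.predicate == "numeric-range":
            col = work[clause.name]
            work = work[(col >= clause.low) & (col <= clause.high)]
        else:
            # cells carry no labels in these fixtures
            keep = clause.predicate == "label-absence"
            if not keep:
                work = work.iloc[0:0]

    # step 2: aggregation (grouping level only), per-axis non-missing
    if state.level == "grouping":
        agg = _AGG[state.aggregation]
        rows = []
        for gene, sub in work.groupby("geneID"):
            xs = sub[state.x_feature].dropna().to_numpy()
            if not xs.size:
                continue
            if state.y_feature is not None:
                ys = sub[state.y_feature].dropna().to_numpy()
                if not ys.size:
                    continue
                rows.append((gene, float(agg(xs)), float(agg(ys))))
            else:
                rows.append((gene, float(agg(xs)), None))
        table = rows
        key_of = lambda r: (r[0],)  # noqa: E731
    else:
        cols = [state.x_feature]
        if state.y_feature is not None:
            cols.append(state.y_feature)
        sub = work.dropna(subset=cols)
        table = [(row.cellID, float(getattr(row, state.x_feature)),
                  float(getattr(row, state.y_feature))
                  if state.y_feature else None, row.geneID)
                 for row in sub.itertuples()]
        key_of = lambda r: (r[0],)  # noqa: E731

    # step 3: grouping-level filters
    gene_filters = [c for c in state.filters if c.target_kind == "Gene"]
    if gene_filters:
        def gene_ok(gene):
            for clause in gene_filters:
                if clause.predicate == "label-presence":
                    if gene not in genes_with_label(labels, clause.name):
                        return False
                elif clause.predicate == "label-absence":
                    if gene in genes_with_label(labels, clause.name):
                        return False
                else:  # genes carry no numeric properties in the fixtures
                    return False
            return True
        if state.level == "grouping":
            table = [r for r in table if gene_ok(r[0])]
        else:
            table = [r for r in table if gene_ok(r[3])]

    # step 4: transforms
    def transform(values, how):
        if how == "linear":
            return values, False
        vals = [v for v in values if v is not None]
        if any(v <= 0 for v in vals):
            return values, True
        return [None if v is None else float(np.log10(v))
                for v in values], False

    xs, x_err = transform([r[1] for r in table], state.x_transform)
    ys, y_err = transform([r[2] for r in table], state.y_transform
                          if state.y_feature else "linear")
    if x_err or y_err:
        return None, True

    # step 5: selection (closed rectangle, displayed coordinates)
    out = []
    for r, x, y in zip(table, xs, ys):
        if state.selection is not None:
            sel = state.selection
            if not (sel.x_min <= x <= sel.x_max):
                continue
            if y is not None and sel.y_min is not None \
                    and not (sel.y_min <= y <= sel.y_max):
                continue
        out.append((key_of(r), x, y))
    out.sort(key=lambda r: r[0])
    return out, False
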