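"""Trait-table input and fitted-model output.

Traits come in as a two-column species/value table (CSV or TSV, header
optional); fits go out as ``rates.csv`` (node_id, label, height, sigma2),
``fit.json`` (scalars and options) and ``rates.nwk`` — the input tree with
per-node ``[&sigma2=...]`` annotations in extended-Newick comment syntax, so
standard Newick readers still parse the file.  Floats are serialized with 17
significant digits for lossless round-trips.
"""

from __future__ import annotations

import csv
import io as _io
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .fit import FittedModel
from .phylo import Phylogeny, node_heights

logger = logging.getLogger(__name__)

__all__ = ["read_traits", "write_fit", "read_rates_csv"]


def read_traits(path: str | Path, tree: Phylogeny) -> np.ndarray:
    """Read a two-column (species, value) CSV/TSV and align it to tip order.

    The delimiter (comma or tab) and an optional header row are detected
    automatically.  Every tree tip must appear exactly once; extra species
    are dropped with a warning; a missing tip or a non-numeric value is an
    error naming the offender.
    """
    text = Path(path).read_text()
    delim = "\t" if text.splitlines()[0].count("\t") else ","
    rows = [r for r in csv.reader(_io.StringIO(text), delimiter=delim) if r]
    if any(len(r) < 2 for r in rows):
        bad = next(r for r in rows if len(r) < 2)
        raise ValueError(f"expected two columns (species, value); got row {bad!r}")

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    if rows and not _numeric(rows[0][1]):
        rows = rows[1:]  # header

    values: dict[str, float] = {}
    for r in rows:
        name = r[0].strip()
        if not _numeric(r[1]):
            raise ValueError(f"non-numeric trait value {r[1]!r} for species {name!r}")
        values[name] = float(r[1])

    missing = [t for t in tree.tip_labels if t not in values]
    if missing:
        raise ValueError(f"tips missing from trait file: {missing}")
    extra = sorted(set(values) - set(tree.tip_labels))
    if extra:
        logger.warning("dropping %d species not in the tree: %s", len(extra), extra)
    return np.array([values[t] for t in tree.tip_labels])


def _g17(v: float) -> str:
    return format(float(v), ".17g")


def write_fit(model: FittedModel, outdir: str | Path) -> dict[str, Path]:
    """Write ``rates.csv``, ``fit.json`` and ``rates.nwk`` for one fit."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = model.tree
    h = node_heights(tree)

    rates_csv = outdir / "rates.csv"
    with rates_csv.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "label", "height", "sigma2"])
        for v in range(1, tree.n_nodes + 1):
            label = tree.tip_labels[v - 1] if v <= tree.n else ""
            w.writerow([v, label, _g17(h[v]), _g17(model.sigma2[v])])

    fit_json = outdir / "fit.json"
    payload = {
        "software": "ratesmooth",
        "version": __version__,
        "lambda": model.lam,
        "n_tips": tree.n,
        "n_internal": tree.m,
        "x0_hat": model.x0_hat,
        "s0_hat": model.s0_hat,
        "logL": model.logL,
        "penalty": model.penalty,
        "penalized_logL": model.penalized_logL,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "n_fev": model.n_fev,
        "mean_sigma2_edges": model.mean_sigma2_edges,
        "mean_sigma2_nodes": model.mean_sigma2_nodes,
    }
    fit_json.write_text(json.dumps(payload, indent=2) + "\n")

    rates_nwk = outdir / "rates.nwk"
    notes = {v: f"[&sigma2={_g17(model.sigma2[v])}]" for v in model.sigma2}
    rates_nwk.write_text(tree.newick(annotations=notes) + "\n")

    return {"rates.csv": rates_csv, "fit.json": fit_json, "rates.nwk": rates_nwk}


def read_rates_csv(path: str | Path) -> dict[int, float]:
    """Read back the per-node sigma^2 map from a ``rates.csv``."""
    out: dict[int, float] = {}
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            out[int(row["node_id"])] = float(row["sigma2"])
    return out
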