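"""Readers and writers for the package's tab-separated interchange formats.

Every writer here has a matching reader and the pair round-trips exactly
(floats are serialized with ``repr``-level precision).

Formats:

* formula:   ``herb<TAB>ratio`` with header;
* abundance: ``herb<TAB>compound<TAB>abundance`` with header;
* catalog:   ``compound<TAB>protein<TAB>probability<TAB>provenance`` with header;
* weights:   ``protein<TAB>weight`` with header (optional ``raw_weight`` column);
* source scores: ``symbol`` column plus one column per source, empty cell = missing;
* symbol list: one symbol per line, no header;
* integrated scores: ``symbol<TAB>targetscore<TAB>rank`` with header.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .disease import IntegratedScoreTable
from .herbs import CompoundAbundanceTable, FormulaComposition, InteractionCatalog
from .weighting import WeightedProteinSet

__all__ = [
    "read_formula_tsv",
    "write_formula_tsv",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_catalog_tsv",
    "write_catalog_tsv",
    "read_weights_tsv",
    "write_weights_tsv",
    "read_source_table",
    "write_source_table",
    "read_symbol_list",
    "write_integrated_tsv",
    "read_integrated_tsv",
]

_FLOAT = "%.17g"


def write_formula_tsv(
    formula: FormulaComposition, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("herb\tratio\n")
        for herb in sorted(formula.ratios):
            fh.write(f"{herb}\t{_FLOAT % formula.ratios[herb]}\n")


def read_formula_tsv(path: str | Path, name: str | None = None) -> FormulaComposition:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"herb": str})
    _need(frame, ("herb", "ratio"), path)
    return FormulaComposition(
        name or Path(path).stem, dict(zip(frame["herb"], frame["ratio"].astype(float)))
    )


def write_abundance_tsv(table: CompoundAbundanceTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("herb\tcompound\tabundance\n")
        for herb, compound in sorted(table.abundance):
            fh.write(
                f"{herb}\t{compound}\t{_FLOAT % table.abundance[(herb, compound)]}\n"
            )


def read_abundance_tsv(path: str | Path) -> CompoundAbundanceTable:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"herb": str, "compound": str})
    _need(frame, ("herb", "compound", "abundance"), path)
    pairs = list(zip(frame["herb"], frame["compound"]))
    if len(pairs) != len(set(pairs)):
        raise ValueError(f"{path}: duplicate (herb, compound) rows")
    return CompoundAbundanceTable(dict(zip(pairs, frame["abundance"].astype(float))))


def write_catalog_tsv(catalog: InteractionCatalog, path: str | Path) -> None:
    prov = catalog.provenance or {}
    with open(path, "w") as fh:
        fh.write("compound\tprotein\tprobability\tprovenance\n")
        for compound, protein in sorted(catalog.confidence):
            p = catalog.confidence[(compound, protein)]
            tag = prov.get((compound, protein), "predicted")
            fh.write(f"{compound}\t{protein}\t{_FLOAT % p}\t{tag}\n")


def read_catalog_tsv(path: str | Path) -> InteractionCatalog:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"compound": str, "protein": str})
    _need(frame, ("compound", "protein", "probability"), path)
    keys = list(zip(frame["compound"], frame["protein"]))
    confidence = dict(zip(keys, frame["probability"].astype(float)))
    provenance = (
        dict(zip(keys, frame["provenance"])) if "provenance" in frame.columns else None
    )
    return InteractionCatalog(confidence, provenance)


def write_weights_tsv(
    weights: WeightedProteinSet,
    path: str | Path,
    raw: dict[str, float] | None = None,
) -> None:
    with open(path, "w") as fh:
        if raw is not None:
            fh.write("protein\traw_weight\tnorm_weight\n")
            for protein in sorted(weights.weights):
                fh.write(
                    f"{protein}\t{_FLOAT % raw[protein]}\t"
                    f"{_FLOAT % weights.weights[protein]}\n"
                )
        else:
            fh.write("protein\tweight\n")
            for protein in sorted(weights.weights):
                fh.write(f"{protein}\t{_FLOAT % weights.weights[protein]}\n")


def read_weights_tsv(path: str | Path, label: str = "unlabeled") -> WeightedProteinSet:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"protein": str})
    if "protein" not in frame.columns:
        raise ValueError(f"{path}: missing 'protein' column")
    col = "norm_weight" if "norm_weight" in frame.columns else "weight"
    if col not in frame.columns:
        raise ValueError(f"{path}: missing weight column ('weight' or 'norm_weight')")
    return WeightedProteinSet(
        dict(zip(frame["protein"], frame[col].astype(float))), label
    )


def write_source_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.index.name = "symbol"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_source_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"symbol": str})
    _need(frame, ("symbol",), path)
    return frame.set_index("symbol")


def read_symbol_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def write_integrated_tsv(table: IntegratedScoreTable, path: str | Path) -> None:
    frame = table.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# scheme: {table.scheme}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_integrated_tsv(path: str | Path) -> IntegratedScoreTable:
    scheme = "multiplicative"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# scheme:"):
            scheme = first.split(":", 1)[1].strip()
            frame = pd.read_csv(fh, sep="\t", float_precision="round_trip", dtype={"symbol": str})
        else:
            fh.seek(0)
            frame = pd.read_csv(fh, sep="\t", float_precision="round_trip", dtype={"symbol": str})
    _need(frame, ("symbol", "targetscore"), path)
    return IntegratedScoreTable(
        pd.Series(
            frame["targetscore"].astype(float).to_numpy(), index=frame["symbol"]
        ),
        scheme,
    )


def _need(frame: pd.DataFrame, columns: tuple[str, ...], path: str | Path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
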