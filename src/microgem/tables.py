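"""Readers and writers for the tabular interchange formats.

All tables are UTF-8 TSV with a header row. Pathway reaction sets use
the GMT convention: one set per line, ``set_id<TAB>description<TAB>member...``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

TAXONOMY_LEVELS = ("genus", "family", "order", "class", "phylum")
UNCLASSIFIED = "unclassified"


def read_catalog_table(path: str | Path) -> list[tuple[str, set[str]]]:
    """Gene catalogue TSV: columns ``gene_id`` and semicolon-joined ``ko_terms``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = []
    for gene, kos in zip(df["gene_id"], df["ko_terms"]):
        terms = {t.strip() for t in kos.split(";") if t.strip()}
        entries.append((gene, terms))
    return entries


def write_catalog_table(entries, path: str | Path) -> None:
    rows = [(g, ";".join(sorted(kos))) for g, kos in entries]
    pd.DataFrame(rows, columns=["gene_id", "ko_terms"]).to_csv(path, sep="\t", index=False)


def read_ko_map(path: str | Path) -> dict[str, set[str]]:
    """KO-to-reaction TSV: one ``ko_id<TAB>rxn_id`` pair per line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping: dict[str, set[str]] = {}
    for ko, rxn in zip(df["ko_id"], df["rxn_id"]):
        mapping.setdefault(ko, set()).add(rxn)
    return mapping


def write_ko_map(mapping: dict[str, set[str]], path: str | Path) -> None:
    rows = [(ko, rxn) for ko in sorted(mapping) for rxn in sorted(mapping[ko])]
    pd.DataFrame(rows, columns=["ko_id", "rxn_id"]).to_csv(path, sep="\t", index=False)


def read_msp_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """MSP membership TSV: one ``msp_id<TAB>gene_id`` pair per line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    sets: dict[str, set[str]] = {}
    for msp, gene in zip(df["msp_id"], df["gene_id"]):
        sets.setdefault(msp, set()).add(gene)
    return sets


def write_msp_gene_sets(sets: dict[str, set[str]], path: str | Path) -> None:
    rows = [(m, g) for m in sets for g in sorted(sets[m])]
    pd.DataFrame(rows, columns=["msp_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Taxonomy TSV indexed by msp_id with species + the five pooling levels."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("msp_id")
    missing = [c for c in ("species",) + TAXONOMY_LEVELS if c not in df.columns]
    if missing:
        raise ValueError(f"taxonomy table missing columns: {missing}")
    return df.fillna(UNCLASSIFIED)


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    tax.to_csv(path, sep="\t", index_label="msp_id")


def read_abundance(path: str | Path) -> pd.DataFrame:
    """MSP x sample relative-abundance matrix, first column ``msp_id``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative abundances")
    return df


def write_abundance(ab: pd.DataFrame, path: str | Path) -> None:
    ab.to_csv(path, sep="\t", index_label="msp_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """A labelled numeric matrix TSV (reactions/metrics x columns)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_diet_table(path: str | Path) -> dict[str, float]:
    """Diet TSV: ``metabolite_or_exchange_id<TAB>uptake_bound`` (positive magnitudes)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    bounds = dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))
    bad = [k for k, v in bounds.items() if v <= 0]
    if bad:
        raise ValueError(f"{path}: non-positive uptake bounds for {bad}")
    return bounds


def write_diet_table(uptake_bounds: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        sorted(uptake_bounds.items()), columns=["metabolite_or_exchange_id", "uptake_bound"]
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT reaction-set file: ``pathway_id<TAB>description<TAB>rxn...`` per line."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        sets[fields[0]] = {f for f in fields[2:] if f}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    lines = [
        "\t".join([pid, descriptions.get(pid, pid)] + sorted(members))
        for pid, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_group_labels(path: str | Path) -> pd.Series:
    """Sample grouping TSV: columns ``sample`` and ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index("sample")["group"]


def write_group_labels(groups: pd.Series, path: str | Path) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="sample")
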