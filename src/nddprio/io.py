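"""TSV readers and writers for the pipeline's file dialects.

All tables are plain tab-separated text with "." for missing values.  The
annotated-variant table has one row per variant per proband with the fixed
column set below.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

from .catalog import EvidenceRecord
from .coexpr import ExpressionMatrix
from .tada import TadaHyperparams
from .variants import (
    AnnotatedVariant,
    Effect,
    GeneCountTable,
    Genotype,
    Sex,
    COUNT_COLUMNS,
)

MISSING = "."

VARIANT_COLUMNS = [
    "variant_id",
    "family_id",
    "sample_role",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "reve",
    "af_gnomad",
    "af_exac",
    "af_inhouse",
    "gt_proband",
    "gt_father",
    "gt_mother",
    "proband_sex",
]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == MISSING:
        return None
    return float(value)


def read_variants(path: str | Path) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    required = [c for c in VARIANT_COLUMNS if c not in ("variant_id", "sample_role")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {', '.join(missing)}")
    variants = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        variants.append(
            AnnotatedVariant(
                variant_id=str(d.get("variant_id") or f"row{i}"),
                chrom=d["chrom"],
                pos=int(d["pos"]),
                ref=d["ref"],
                alt=d["alt"],
                gene=d["gene"] if pd.notna(d["gene"]) else "",
                effect=Effect(d["effect"]),
                reve=_opt_float(d.get("reve")),
                af_gnomad=_opt_float(d.get("af_gnomad")),
                af_exac=_opt_float(d.get("af_exac")),
                af_inhouse=_opt_float(d.get("af_inhouse")),
                gt_proband=Genotype(d["gt_proband"]) if pd.notna(d["gt_proband"]) else Genotype.missing,
                gt_father=Genotype(d["gt_father"]) if pd.notna(d["gt_father"]) else Genotype.missing,
                gt_mother=Genotype(d["gt_mother"]) if pd.notna(d["gt_mother"]) else Genotype.missing,
                proband_sex=Sex(d["proband_sex"]) if pd.notna(d["proband_sex"]) else Sex.unknown,
                family_id=str(d.get("family_id") or ""),
            )
        )
    return variants


def write_variants(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in VARIANT_COLUMNS:
        if col not in out.columns:
            out[col] = MISSING
    out = out[VARIANT_COLUMNS]
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=MISSING)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[MISSING])


def write_gene_counts(table: GeneCountTable, path: str | Path) -> None:
    """Gene-count TSV with cohort sizes in comment header lines."""
    with open(path, "w") as fh:
        fh.write(f"# n_trios={table.n_trios}\n")
        fh.write(f"# n_cases={table.n_cases}\n")
        fh.write(f"# n_controls={table.n_controls}\n")
        table.counts.to_csv(fh, sep="\t")


def read_gene_counts(path: str | Path) -> GeneCountTable:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            sizes[key.strip()] = int(val)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    missing = {"n_trios", "n_cases", "n_controls"} - sizes.keys()
    if missing:
        raise ValueError(f"gene-count file missing cohort sizes: {', '.join(sorted(missing))}")
    return GeneCountTable(
        df[list(COUNT_COLUMNS)],
        n_trios=sizes["n_trios"],
        n_cases=sizes["n_cases"],
        n_controls=sizes["n_controls"],
    )


def read_mutation_rates(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    for col in ("mu_PTV", "mu_Dmis"):
        if col not in df.columns:
            raise ValueError(f"mutation-rate table missing column {col}")
    return df


def read_expression(values_path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    if "cortical" in metadata.columns:
        metadata["cortical"] = metadata["cortical"].astype(bool)
    return ExpressionMatrix(values, metadata)


def read_gene_set(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_ppi(path: str | Path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_a", "gene_b", "miscore"):
        if col not in df.columns:
            raise ValueError(f"PPI table missing column {col}")
    return list(df[["gene_a", "gene_b", "miscore"]].itertuples(index=False, name=None))


def read_constraint(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    for col in ("pli", "rvis"):
        if col not in df.columns:
            raise ValueError(f"constraint table missing column {col}")
    return df


def read_evidence(path: str | Path) -> dict[str, EvidenceRecord]:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=[MISSING], keep_default_na=False)
    records = {}
    for gene, row in df.iterrows():
        pubs = row.get("publications")
        pub_set = (
            frozenset(p for p in str(pubs).split(";") if p) if pd.notna(pubs) and pubs else frozenset()
        )
        records[str(gene)] = EvidenceRecord(
            gene=str(gene),
            in_publication_lists=pub_set,
            omim_ndd=str(row.get("omim_ndd", "0")) in {"1", "True", "true"},
            sfari_category=str(row.get("sfari_category", "none")) if pd.notna(row.get("sfari_category")) else "none",
            pubmed_support=str(row.get("pubmed_support", "0")) in {"1", "True", "true"},
        )
    return records


def read_hyperparams(path: str | Path) -> TadaHyperparams:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return TadaHyperparams.from_dict(data)


def write_hyperparams(params: TadaHyperparams, path: str | Path) -> None:
    data = {
        "gamma_bar_dn": dict(params.gamma_bar_dn),
        "beta_dn": dict(params.beta_dn),
        "gamma_bar_cc": dict(params.gamma_bar_cc),
        "beta_cc": dict(params.beta_cc),
        "rho": dict(params.rho),
        "nu": dict(params.nu),
        "pi": params.pi,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def write_edge_list(graph: nx.Graph, path: str | Path, attr: str = "r") -> None:
    rows = [
        {"gene_a": min(u, v), "gene_b": max(u, v), attr: data.get(attr)}
        for u, v, data in graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", attr])
    df = df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_edge_list(path: str | Path, attr: str = "r") -> nx.Graph:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, **{attr: getattr(row, attr, None)})
    return g


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    # GraphML rejects None attribute values
    g = graph.copy()
    for _, _, data in g.edges(data=True):
        for key in [k for k, v in data.items() if v is None]:
            del data[key]
    nx.write_graphml(g, path)
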