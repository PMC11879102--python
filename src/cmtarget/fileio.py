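"""File formats, run configuration and the end-to-end pipeline.

All tables are tab-separated UTF-8; lines starting with ``#`` are comments;
missing values are written as ``NA``.  Genes are opaque case-sensitive
strings — no identifier munging happens anywhere.  Writers emit a header row
naming every column and readers validate it, so a file produced by one stage
is always safe input for the next.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .binding import BindingPair, BindingScore
from .connectivity import ConnectivityResult, RankedQuery
from .enrichment import EnrichmentResult, GeneSetCollection, annotate_pathway, ora
from .signatures import (
    ConsensusProfile,
    ExpressionSignature,
    TargetGeneSignature,
    build_consensus,
    extract_signature,
)
from .targets import (
    TargetCall,
    build_component_network,
    call_effect_targets,
    classify_targets,
    make_calls,
    reversal_targets,
    top_components,
    top_targets,
)

logger = logging.getLogger(__name__)

NA = "NA"


def _read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA], **kwargs)


def _check_header(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------- RNK queries

def read_rnk(path, label: str | None = None) -> RankedQuery:
    """Read a two-column RNK file (gene_id TAB metric, no header).

    Rows are re-sorted descending when needed (with a warning); duplicate
    genes and non-numeric metrics are rejected with the offending line.
    """
    path = Path(path)
    genes: list[str] = []
    metrics: list[float] = []
    seen: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            gene, raw = parts
            if gene in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate gene {gene!r} "
                    f"(first seen on line {seen[gene]})"
                )
            try:
                metric = float(raw)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric metric {raw!r}"
                ) from None
            seen[gene] = lineno
            genes.append(gene)
            metrics.append(metric)
    if not genes:
        raise ValueError(f"{path}: empty RNK file")
    arr = np.asarray(metrics)
    if np.any(np.diff(arr) > 0):
        logger.warning("%s: not sorted descending; sorting", path)
        return RankedQuery.from_values(label or path.stem, genes, arr)
    return RankedQuery(label or path.stem, genes, arr)


def write_rnk(query: RankedQuery, path) -> None:
    with Path(path).open("w") as fh:
        for g, m in zip(query.gene_ids, query.metrics):
            fh.write(f"{g}\t{m:.6g}\n")


# ------------------------------------------------------- profiles & metadata

def read_profiles(profiles_path, meta_path) -> list[ExpressionSignature]:
    """Profile matrix (rows=genes, columns=signature_ids) + metadata TSV."""
    mat = _read_table(profiles_path, index_col=0)
    meta = _read_table(meta_path, dtype=str)
    _check_header(meta, ["signature_id", "perturbagen_id", "target_id"], meta_path)
    genes = [str(g) for g in mat.index]
    sigs = []
    for _, row in meta.iterrows():
        sid = row["signature_id"]
        if sid not in mat.columns:
            raise ValueError(f"{profiles_path}: no column for signature {sid!r}")
        sigs.append(
            ExpressionSignature(
                signature_id=sid,
                gene_ids=genes,
                values=mat[sid].to_numpy(dtype=float),
                perturbagen_id=row["perturbagen_id"],
                target_id=row["target_id"],
            )
        )
    if not sigs:
        raise ValueError(f"{meta_path}: no signatures described")
    return sigs


def write_profiles(signatures: Sequence[ExpressionSignature], profiles_path,
                   meta_path) -> None:
    mat = pd.DataFrame(
        {s.signature_id: s.values for s in signatures},
        index=signatures[0].gene_ids,
    )
    mat.index.name = "gene_id"
    mat.to_csv(profiles_path, sep="\t", float_format="%.6g")
    meta = pd.DataFrame(
        {
            "signature_id": [s.signature_id for s in signatures],
            "perturbagen_id": [s.perturbagen_id for s in signatures],
            "perturbagen_type": ["compound"] * len(signatures),
            "target_id": [s.target_id for s in signatures],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)


# ------------------------------------------------------------ signature library

SIGLIB_COLUMNS = ["target_id", "direction", "gene_id", "rank"]


def write_signature_library(sigs: Sequence[TargetGeneSignature], path) -> None:
    rows = []
    for sig in sigs:
        rows.extend(
            {"target_id": sig.target_id, "direction": "up", "gene_id": g, "rank": i + 1}
            for i, g in enumerate(sig.t_up)
        )
        rows.extend(
            {"target_id": sig.target_id, "direction": "down", "gene_id": g,
             "rank": i + 1}
            for i, g in enumerate(sig.t_down)
        )
    pd.DataFrame(rows, columns=SIGLIB_COLUMNS).to_csv(path, sep="\t", index=False)


def read_signature_library(path) -> list[TargetGeneSignature]:
    df = _read_table(path, dtype={"target_id": str, "gene_id": str})
    _check_header(df, SIGLIB_COLUMNS, path)
    sigs = []
    for target_id, grp in df.groupby("target_id", sort=True):
        up = grp[grp["direction"] == "up"].sort_values("rank")["gene_id"].tolist()
        down = grp[grp["direction"] == "down"].sort_values("rank")["gene_id"].tolist()
        sigs.append(TargetGeneSignature(str(target_id), up, down))
    if not sigs:
        raise ValueError(f"{path}: empty signature library")
    return sigs


def write_consensus_profiles(profiles: Sequence[ConsensusProfile], path) -> None:
    mat = pd.DataFrame(
        {p.target_id: pd.Series(p.values, index=p.gene_ids) for p in profiles}
    )
    mat.index.name = "gene_id"
    mat.to_csv(path, sep="\t", float_format="%.6g", na_rep=NA)


# ------------------------------------------------------------ connectivity IO

RESULT_COLUMNS = ["target_id", "ets", "p", "nets", "fdr", "up_matched",
                  "down_matched"]


def write_results(results: Sequence[ConnectivityResult], path) -> None:
    df = pd.DataFrame(
        {
            "target_id": [r.target_id for r in results],
            "ets": [r.ets for r in results],
            "p": [r.p for r in results],
            "nets": [r.nets for r in results],
            "fdr": [r.fdr for r in results],
            "up_matched": [r.n_genes_matched_up for r in results],
            "down_matched": [r.n_genes_matched_down for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> list[ConnectivityResult]:
    df = _read_table(path, dtype={"target_id": str})
    _check_header(df, RESULT_COLUMNS, path)
    return [
        ConnectivityResult(
            target_id=row.target_id,
            ets=float(row.ets),
            p=float(row.p),
            nets=float(row.nets),
            fdr=float(row.fdr),
            n_genes_matched_up=int(row.up_matched),
            n_genes_matched_down=int(row.down_matched),
        )
        for row in df.itertuples()
    ]


# ------------------------------------------------------------------ binding IO

def read_compounds(path) -> dict[str, str]:
    df = _read_table(path, dtype=str)
    _check_header(df, ["compound_id", "smiles"], path)
    if df.empty:
        raise ValueError(f"{path}: empty compounds table")
    return dict(zip(df["compound_id"], df["smiles"]))


def write_compounds(compounds: dict[str, str], path) -> None:
    pd.DataFrame(
        {"compound_id": list(compounds), "smiles": list(compounds.values())}
    ).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """Protein sequences keyed by record id (wrapped lines concatenated)."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(proteins: dict[str, str], path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_pairs(
    path, compounds: dict[str, str], proteins: dict[str, str],
    labelled: bool = True,
) -> list[BindingPair]:
    df = _read_table(path, dtype={"compound_id": str, "protein_id": str})
    _check_header(df, ["compound_id", "protein_id"], path)
    pairs = []
    for row in df.itertuples():
        if row.compound_id not in compounds:
            raise ValueError(f"{path}: unknown compound {row.compound_id!r}")
        if row.protein_id not in proteins:
            raise ValueError(f"{path}: unknown protein {row.protein_id!r}")
        raw_label = getattr(row, "label", None) if labelled else None
        label = None if raw_label is None or pd.isna(raw_label) else int(raw_label)
        pairs.append(
            BindingPair(
                row.compound_id,
                compounds[row.compound_id],
                row.protein_id,
                proteins[row.protein_id],
                label,
            )
        )
    if not pairs:
        raise ValueError(f"{path}: empty pairs table")
    return pairs


def write_pairs(pairs: Sequence[BindingPair], path) -> None:
    pd.DataFrame(
        {
            "compound_id": [p.compound_id for p in pairs],
            "protein_id": [p.protein_id for p in pairs],
            "label": [p.label if p.label is not None else NA for p in pairs],
        }
    ).to_csv(path, sep="\t", index=False)


def write_scores(scores: Sequence[BindingScore], path) -> None:
    pd.DataFrame(
        {
            "compound_id": [s.compound_id for s in scores],
            "protein_id": [s.protein_id for s in scores],
            "score": [s.score for s in scores],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_scores(path) -> list[BindingScore]:
    df = _read_table(path, dtype={"compound_id": str, "protein_id": str})
    _check_header(df, ["compound_id", "protein_id", "score"], path)
    return [
        BindingScore(row.compound_id, row.protein_id, float(row.score))
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------- GMT

def read_gmt(path) -> GeneSetCollection:
    """Standard GMT: name TAB description TAB member genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member"
                )
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with Path(path).open("w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# --------------------------------------------------------------- calls & nets

CALL_COLUMNS = ["target_id", "role", "nets_drug", "nets_disease", "fdr_drug",
                "fdr_disease"]


def _role_string(c: TargetCall) -> str:
    roles = [
        name
        for name in ("effect", "binding", "direct", "indirect", "therapeutic")
        if getattr(c, name)
    ]
    return ",".join(roles) if roles else "none"


def write_calls(calls: Sequence[TargetCall], path) -> None:
    def fmt(x: float) -> str:
        return NA if np.isnan(x) else f"{x:.6g}"

    with Path(path).open("w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.target_id,
                        _role_string(c),
                        fmt(c.nets_drug),
                        fmt(c.nets_disease),
                        fmt(c.fdr_drug),
                        fmt(c.fdr_disease),
                    ]
                )
                + "\n"
            )


def write_edges(edges: Iterable[tuple[str, str]], path) -> None:
    pd.DataFrame(sorted(edges), columns=["compound_id", "target_id"]).to_csv(
        path, sep="\t", index=False
    )


ENRICH_COLUMNS = ["pathway_id", "k", "m", "K", "N", "p", "fdr",
                  "direct_members", "indirect_members"]


def write_enrichment(results: Sequence[EnrichmentResult], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(ENRICH_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.pathway_id,
                        str(r.k), str(r.m), str(r.K), str(r.N),
                        f"{r.p:.6g}", f"{r.fdr:.6g}",
                        ",".join(r.direct_members) or NA,
                        ",".join(r.indirect_members) or NA,
                    ]
                )
                + "\n"
            )


# ------------------------------------------------------------------ pipeline

@dataclasses.dataclass
class RunConfig:
    """Paths, thresholds and seeds for a full drug-vs-disease run."""

    siglib: str
    drug_rnk: str
    disease_rnk: str
    outdir: str
    binding_scores: str | None = None
    gmt: str | None = None
    fdr_threshold: float = 0.05
    binding_threshold: float = 0.90
    abs_nets_threshold: float = 4.0
    top_k: int = 100
    n_perm: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 <= self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in [0, 1]")
        if not 0 <= self.binding_threshold <= 1:
            raise ValueError("binding_threshold must be in [0, 1]")
        if self.abs_nets_threshold < 0:
            raise ValueError("abs_nets_threshold must be >= 0")
        if self.top_k <= 0 or self.n_perm <= 0:
            raise ValueError("top_k and n_perm must be positive")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Score drug and disease, classify targets, build the network, enrich.

    Writes every stage table plus a manifest (package version, seeds,
    thresholds, input checksums) into the run directory; a second run with
    the same inputs and seeds reproduces the tables byte for byte.  With no
    binding scores every effect target degrades to indirect (warned).
    """
    from .connectivity import score_query

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load inputs"
    try:
        library = read_signature_library(config.siglib)
        drug_q = read_rnk(config.drug_rnk, label="drug")
        disease_q = read_rnk(config.disease_rnk, label="disease")
        scores = read_scores(config.binding_scores) if config.binding_scores else None
        collection = read_gmt(config.gmt) if config.gmt else None

        stage = "score drug query"
        drug = score_query(drug_q, library, n_perm=config.n_perm, seed=config.seed)
        write_results(drug, outdir / "drug_results.tsv")

        stage = "score disease query"
        disease = score_query(
            disease_q, library, n_perm=config.n_perm, seed=config.seed + 1
        )
        write_results(disease, outdir / "disease_results.tsv")

        stage = "classify targets"
        if scores is None:
            logger.warning(
                "no binding scores supplied: every effect target is indirect"
            )
            binding_calls: set[tuple[str, str]] = set()
        else:
            from .binding import call_binding_targets

            binding_calls = call_binding_targets(scores, config.binding_threshold)
        binding_set = {t for _, t in binding_calls}
        calls = make_calls(drug, disease, binding_set, config.fdr_threshold)
        write_calls(calls, outdir / "target_calls.tsv")
        effect = call_effect_targets(drug, config.fdr_threshold)
        direct, indirect = classify_targets(effect, binding_set)
        therapeutic = reversal_targets(drug, disease, config.fdr_threshold)

        stage = "component network"
        network = build_component_network(binding_calls, direct)
        write_edges(network.edges, outdir / "component_network.tsv")
        ranked = top_components(network, config.top_k)
        strong = top_targets(drug, config.abs_nets_threshold)
        (outdir / "top_components.txt").write_text(
            "".join(f"{c}\t{network.degree(c)}\n" for c in ranked)
        )
        (outdir / "top_targets.txt").write_text(
            "".join(f"{t}\n" for t in sorted(strong))
        )

        stage = "enrichment"
        if collection is not None and therapeutic:
            enriched = [
                annotate_pathway(r, direct, indirect)
                for r in ora(therapeutic, collection, config.fdr_threshold)
            ]
            write_enrichment(enriched, outdir / "enrichment.tsv")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage: {stage}: {exc}") from exc

    manifest = {
        "package": "cmtarget",
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "thresholds": {
            "fdr": config.fdr_threshold,
            "binding": config.binding_threshold,
            "abs_nets": config.abs_nets_threshold,
            "top_k": config.top_k,
        },
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in {
                "siglib": config.siglib,
                "drug_rnk": config.drug_rnk,
                "disease_rnk": config.disease_rnk,
                "binding_scores": config.binding_scores,
                "gmt": config.gmt,
            }.items()
            if p
        },
        "counts": {
            "targets_scored": len(drug),
            "effect": len(effect),
            "direct": len(direct),
            "indirect": len(indirect),
            "therapeutic": len(therapeutic),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


def build_signature_library(
    signatures: Sequence[ExpressionSignature], n: int
) -> tuple[list[TargetGeneSignature], list[ConsensusProfile]]:
    """Group replicates by target, build consensus profiles, extract signatures."""
    by_target: dict[str, list[ExpressionSignature]] = {}
    for s in signatures:
        by_target.setdefault(s.target_id, []).append(s)
    profiles = [build_consensus(group) for group in by_target.values()]
    sigs = [extract_signature(p, n) for p in profiles]
    return sigs, profiles
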