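"""Stage-wise orchestration of the ACG scan on a directory of gene FASTAs.

Stages: clean -> species-tree GSLS -> branch-moved nulls -> sequence-
convergence calls -> selection tests (sequence-convergent genes only, as in
the original two-step design) -> ACG calls -> ACSMs -> neutral expectations
-> derived-hypothesis tests -> overlap statistics.  Every stage writes a TSV
under the output directory and is skipped when its output already exists, so
a run is resumable.

Null topology sets depend only on the move order, not the hypothesis, so
they are built once per order and shared by all hypotheses and genes; the
per-gene randomness (two-move sampling, bootstrap) derives from the
configured seed and the gene id, which makes results independent of
scheduling order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aa_likelihood import AAModelSpec, gsls
from .codon_selection import (
    background_site_test,
    beb_site_posteriors,
    branch_site_test,
)
from .convergence import (
    DERIVED_SETS,
    NullDistribution,
    bootstrap_threshold,
    call_acg,
    derived_hypothesis_tests,
    find_acsm,
    neutral_expectation,
    percentile_5,
)
from .seqdata import GeneAlignment, clean_alignment, read_gene_alignment
from .stats import build_overlap_table, fisher_two_sided
from .synthetic_data import fixture_species_tree
from .treekit import (
    HYPOTHESES,
    PhyloTree,
    drop_taxa,
    one_move_neighbors,
    parse_newick,
    sample_topologies,
    tree_from_key,
    two_move_neighbors,
)


@dataclass
class PipelineConfig:
    alignment_dir: Path
    out_dir: Path
    tree_file: Path | None = None
    hypotheses: tuple[str, ...] = ("H_noc", "H_foot", "H_rap")
    model: AAModelSpec = field(default_factory=AAModelSpec)
    null_size: int | None = None      # reduced null for desk-scale runs
    n_sample_two_move: int = 1000
    bootstrap_reps: int = 1000
    beb_grid: int = 10
    seed: int = 0
    max_sweeps: int = 30
    subset: tuple[str, ...] | None = None

    def __post_init__(self):
        unknown = set(self.hypotheses) - set(HYPOTHESES)
        if unknown:
            raise ValueError(f"unknown hypotheses: {sorted(unknown)}")
        self.alignment_dir = Path(self.alignment_dir)
        self.out_dir = Path(self.out_dir)

    def species_tree(self) -> PhyloTree:
        if self.tree_file is not None:
            tree = parse_newick(Path(self.tree_file).read_text(), name="H_0")
            for node in tree.nodes():
                if node.parent is not None and node.length is None:
                    node.length = 0.1 if node.is_leaf else 0.05
            return tree
        return fixture_species_tree()


def _gene_seed(seed: int, gene_id: str, salt: str = "") -> int:
    digest = hashlib.sha256(f"{seed}:{gene_id}:{salt}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def load_genes(config: PipelineConfig) -> tuple[list[GeneAlignment], pd.DataFrame]:
    """Stage: read + clean every gene FASTA; returns clean report table."""
    paths = sorted(config.alignment_dir.glob("*.fasta"))
    if config.subset:
        wanted = set(config.subset)
        paths = [p for p in paths if p.stem in wanted]
    if not paths:
        raise FileNotFoundError(f"no FASTA files in {config.alignment_dir}")
    genes, rows = [], []
    for p in paths:
        raw = read_gene_alignment(p)
        cleaned, report = clean_alignment(raw)
        genes.append(cleaned)
        rows.append(
            {
                "gene_id": cleaned.gene_id,
                "L": cleaned.L,
                "removed_gap": report.columns_removed_gap,
                "removed_ambiguous": report.columns_removed_ambiguous,
                "removed_stop": report.columns_removed_stop,
            }
        )
    return genes, pd.DataFrame(rows)


def build_null_sets(config: PipelineConfig, species_tree: PhyloTree):
    """Topology sets per move order, optionally reduced to ``null_size``."""
    orders = {HYPOTHESES[h].n_moves for h in config.hypotheses}
    sets = {}
    one = one_move_neighbors(species_tree)
    if 1 in orders:
        s = one
        if config.null_size and config.null_size < len(s.keys):
            s = sample_topologies(s, config.null_size, config.seed)
        sets[1] = s
    if 2 in orders:
        two = two_move_neighbors(species_tree, one)
        n = config.n_sample_two_move
        if config.null_size:
            n = min(n, config.null_size)
        sets[2] = sample_topologies(two, min(n, len(two.keys)), config.seed)
    return sets


def gsls_stage(config, genes, species_tree, hypothesis_trees, null_sets):
    """dGSLS per gene for every hypothesis and every null topology."""
    out = config.out_dir / "gsls.tsv"
    if out.exists():
        return pd.read_csv(out, sep="\t")
    rows = []
    for gene in genes:
        aa = gene.aa_seqs
        lnl0, _ = gsls(species_tree, aa, config.model, max_sweeps=config.max_sweeps)
        for name, tree in hypothesis_trees.items():
            lnl, _ = gsls(tree, aa, config.model, max_sweeps=config.max_sweeps)
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "tree": name,
                    "kind": "hypothesis",
                    "gsls_h0": lnl0,
                    "gsls_hn": lnl,
                    "delta_gsls": lnl0 - lnl,
                }
            )
        for order, topo_set in null_sets.items():
            for i, key in enumerate(topo_set.keys):
                lnl, _ = gsls(
                    tree_from_key(key), aa, config.model,
                    max_sweeps=config.max_sweeps,
                )
                rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "tree": f"null{order}_{i:05d}",
                        "kind": f"null{order}",
                        "gsls_h0": lnl0,
                        "gsls_hn": lnl,
                        "delta_gsls": lnl0 - lnl,
                    }
                )
    df = pd.DataFrame(rows)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, sep="\t", index=False)
    return df


def convergence_stage(config, gsls_df):
    """Thresholds and sequence-convergence verdicts per gene x hypothesis."""
    out = config.out_dir / "sequence_convergence.tsv"
    if out.exists():
        return pd.read_csv(out, sep="\t")
    rows = []
    for gene_id, sub in gsls_df.groupby("gene_id"):
        nulls = {}
        for order in (1, 2):
            vals = sub.loc[sub["kind"] == f"null{order}", "delta_gsls"].values
            if vals.size == 0:
                continue
            if order == 1:
                thr = percentile_5(vals)
                ci = (float("nan"), float("nan"))
            else:
                thr, ci = bootstrap_threshold(
                    vals,
                    B=config.bootstrap_reps,
                    seed=_gene_seed(config.seed, gene_id, "boot"),
                )
            nulls[order] = (vals, thr, ci)
        for hyp_name in config.hypotheses:
            hyp = HYPOTHESES[hyp_name]
            if hyp.n_moves not in nulls:
                continue
            vals, thr, ci = nulls[hyp.n_moves]
            delta = float(
                sub.loc[sub["tree"] == hyp_name, "delta_gsls"].iloc[0]
            )
            rows.append(
                {
                    "gene_id": gene_id,
                    "hypothesis": hyp_name,
                    "delta_gsls": delta,
                    "threshold": thr,
                    "null_size": int(vals.size),
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "sequence_convergent": bool(delta < thr),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out, sep="\t", index=False)
    return df


def selection_stage(config, genes, species_tree, seq_conv_df):
    """Branch-site and background site tests for sequence-convergent genes."""
    out = config.out_dir / "selection.tsv"
    if out.exists():
        return pd.read_csv(out, sep="\t")
    by_id = {g.gene_id: g for g in genes}
    rows = []
    flagged = seq_conv_df[seq_conv_df["sequence_convergent"]]
    for _, rec in flagged.iterrows():
        gene = by_id[rec["gene_id"]]
        hyp = HYPOTHESES[rec["hypothesis"]]
        fg_lrt, alt, _ = branch_site_test(gene, species_tree, hyp.focal_taxa)
        bg_sig = False
        bg_stat = float("nan")
        if fg_lrt.significant:
            pruned = drop_taxa(species_tree, hyp.focal_taxa)
            bg_lrt, _, _ = background_site_test(gene, pruned)
            bg_sig, bg_stat = bg_lrt.significant, bg_lrt.stat
        rows.append(
            {
                "gene_id": gene.gene_id,
                "hypothesis": hyp.name,
                "fg_stat": fg_lrt.stat,
                "fg_significant": fg_lrt.significant,
                "bg_stat": bg_stat,
                "bg_significant": bg_sig,
                "omega2": alt.params.get("omega2", float("nan")),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "hypothesis", "fg_stat", "fg_significant",
            "bg_stat", "bg_significant", "omega2",
        ],
    )
    df.to_csv(out, sep="\t", index=False)
    return df


def acg_stage(config, seq_conv_df, selection_df):
    """Combine step one and step two into final ACG calls."""
    out = config.out_dir / "acg_calls.tsv"
    if out.exists():
        return pd.read_csv(out, sep="\t")
    sel = selection_df.set_index(["gene_id", "hypothesis"]) if len(selection_df) else None
    rows = []
    for _, rec in seq_conv_df.iterrows():
        key = (rec["gene_id"], rec["hypothesis"])
        fg = bg = False
        if rec["sequence_convergent"] and sel is not None and key in sel.index:
            srow = sel.loc[key]
            fg = bool(srow["fg_significant"])
            bg = bool(srow["bg_significant"])
        null = NullDistribution(
            gene_id=rec["gene_id"],
            move_order=HYPOTHESES[rec["hypothesis"]].n_moves,
            values=np.array([]),
            threshold=float(rec["threshold"]),
        )
        call = call_acg(
            rec["gene_id"], rec["hypothesis"], float(rec["delta_gsls"]),
            null,
            foreground_lrt=_FakeLrt(fg),
            background_lrt=_FakeLrt(bg),
        )
        rows.append(
            {
                "gene_id": call.gene_id,
                "hypothesis": call.hypothesis,
                "delta_gsls": call.delta_gsls,
                "threshold": call.threshold,
                "sequence_convergent": call.sequence_convergent,
                "foreground_selected": call.foreground_selected,
                "background_selected": call.background_selected,
                "excluded_both_models": call.excluded_both_models,
                "is_acg": call.is_acg,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out, sep="\t", index=False)
    return df


class _FakeLrt:
    """Minimal LRT carrier for calls rebuilt from cached significance."""

    def __init__(self, significant: bool):
        self.significant = significant


def acsm_stage(config, genes, species_tree, acg_df):
    """BEB posteriors and ACSM calls for the ACGs."""
    out = config.out_dir / "acsm.tsv"
    if out.exists():
        return pd.read_csv(out, sep="\t")
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for _, rec in acg_df[acg_df["is_acg"]].iterrows():
        gene = by_id[rec["gene_id"]]
        hyp = HYPOTHESES[rec["hypothesis"]]
        _, alt, _ = branch_site_test(gene, species_tree, hyp.focal_taxa)
        beb = beb_site_posteriors(
            alt, gene, species_tree, grid=config.beb_grid
        )
        for call in find_acsm(gene, hyp, beb):
            rows.append(
                {
                    "gene_id": call.gene_id,
                    "hypothesis": call.hypothesis,
                    "site": call.site,
                    "residue": call.residue,
                    "pp_positive": call.pp_positive,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "hypothesis", "site", "residue", "pp_positive"],
    )
    df.to_csv(out, sep="\t", index=False)
    return df


def neutral_stage(config, genes, acg_df):
    """Neutral convergent-site expectations M for the ACGs."""
    out = config.out_dir / "neutral_expectation.tsv"
    if out.exists():
        return pd.read_csv(out, sep="\t")
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for _, rec in acg_df[acg_df["is_acg"]].iterrows():
        gene = by_id[rec["gene_id"]]
        ne = neutral_expectation(gene, rec["hypothesis"])
        rows.append(
            {
                "gene_id": ne.gene_id,
                "hypothesis": ne.hypothesis,
                "D": ne.D,
                "P": ne.P,
                "L": ne.L,
                "M": ne.M,
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "hypothesis", "D", "P", "L", "M"])
    df.to_csv(out, sep="\t", index=False)
    return df


def derived_stage(config, gsls_df):
    """Percentile-rank tests with BH adjustment for derived hypotheses."""
    out = config.out_dir / "derived_tests.tsv"
    if out.exists():
        return pd.read_csv(out, sep="\t")
    rows = []
    for case, members in DERIVED_SETS.items():
        present = [h for h in members if h in set(config.hypotheses)]
        if not present:
            continue
        for gene_id, sub in gsls_df.groupby("gene_id"):
            null_vals = sub.loc[sub["kind"] == "null1", "delta_gsls"].values
            if null_vals.size == 0:
                continue
            deltas = {}
            for h in present:
                hit = sub.loc[sub["tree"] == h, "delta_gsls"]
                if len(hit):
                    deltas[h] = float(hit.iloc[0])
            if not deltas:
                continue
            for t in derived_hypothesis_tests(gene_id, deltas, null_vals):
                rows.append(
                    {
                        "gene_id": t.gene_id,
                        "case": case,
                        "hypothesis": t.hypothesis,
                        "X": t.X,
                        "X_adj": t.X_adj,
                        "significant": t.significant,
                    }
                )
    df = pd.DataFrame(
        rows, columns=["gene_id", "case", "hypothesis", "X", "X_adj", "significant"]
    )
    df.to_csv(out, sep="\t", index=False)
    return df


def overlap_stage(config, acg_df):
    """Union-based overlap tables + Fisher tests between derived pairs."""
    out = config.out_dir / "overlap.json"
    if out.exists():
        return json.loads(out.read_text())
    results = {}
    pairs = [("H_foot_a", "H_foot_b"), ("H_rap_a", "H_rap_b")]
    for ha, hb in pairs:
        if ha not in set(config.hypotheses) or hb not in set(config.hypotheses):
            continue
        def genes_for(h, col):
            sub = acg_df[acg_df["hypothesis"] == h]
            return set(sub.loc[sub[col], "gene_id"])
        acgs_a, acgs_b = genes_for(ha, "is_acg"), genes_for(hb, "is_acg")
        neut_a = {
            g
            for g in genes_for(ha, "sequence_convergent")
            if g not in acgs_a
        }
        neut_b = {
            g
            for g in genes_for(hb, "sequence_convergent")
            if g not in acgs_b
        }
        table = build_overlap_table(acgs_a, acgs_b, neut_a, neut_b)
        test = fisher_two_sided(table)
        results[f"{ha}|{hb}"] = {
            "table": [[table.a, table.b], [table.c, table.d]],
            "p": test.p,
        }
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(results, indent=2))
    return results


@dataclass
class PipelineResult:
    clean_report: pd.DataFrame
    gsls: pd.DataFrame
    sequence_convergence: pd.DataFrame
    selection: pd.DataFrame
    acg_calls: pd.DataFrame
    acsm: pd.DataFrame
    neutral: pd.DataFrame
    derived: pd.DataFrame
    overlap: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order; cached stages are reused."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    species_tree = config.species_tree()
    genes, clean_report = load_genes(config)
    clean_report.to_csv(config.out_dir / "clean_report.tsv", sep="\t", index=False)
    hypothesis_trees = {
        h: HYPOTHESES[h].constrained_tree(species_tree)
        for h in config.hypotheses
    }
    null_sets = build_null_sets(config, species_tree)
    gsls_df = gsls_stage(config, genes, species_tree, hypothesis_trees, null_sets)
    seq_df = convergence_stage(config, gsls_df)
    sel_df = selection_stage(config, genes, species_tree, seq_df)
    acg_df = acg_stage(config, seq_df, sel_df)
    acsm_df = acsm_stage(config, genes, species_tree, acg_df)
    neutral_df = neutral_stage(config, genes, acg_df)
    derived_df = derived_stage(config, gsls_df)
    overlap = overlap_stage(config, acg_df)
    return PipelineResult(
        clean_report, gsls_df, seq_df, sel_df, acg_df, acsm_df,
        neutral_df, derived_df, overlap,
    )
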