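"""End-to-end orchestration: simulate (optional) -> discover -> profile ->
density -> cluster -> polymorph (both directions) -> date -> genic, with all
stage outputs written as plain standard-format files (FASTA/GFF3/BED/TSV/
JSON/Newick) so stages compose via the filesystem.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as ckio
from .clustering import cluster_greedy, singleton_count, subfamily_summary
from .dating import calibrate_rate, divergence_profile, nj_tree, pair_orthologs
from .discovery import DiscoveryConfig, annotate
from .distribution import region_compare, window_counts
from .genic import classify_elements, contexts_to_dataframe, genic_summary
from .polymorphism import call_polymorphisms, calls_to_dataframe, polymorphic_density
from .profile import build_pfm, extract_site_context, site_bias_report
from .seqcore import KmerIndex, gc_fraction
from .simulate import SimulationConfig, simulate_pair

logger = logging.getLogger(__name__)

#: stage thresholds with their conventional defaults (recorded in every run log)
DEFAULT_THRESHOLDS = dict(
    min_score=250.0,
    min_hit_len=50,
    profile_flank=200,
    polymorph_flank=100,
    window_size=100_000,
    id_thresh=0.85,
    cov_thresh=0.85,
    gap_max=20,
    t_split=110_000.0,
)


@dataclass
class RunConfig:
    outdir: str
    simulate: SimulationConfig | None = None
    genome_a: str | None = None
    genome_b: str | None = None
    library: str | None = None
    genes_a: str | None = None
    centromeres_a: str | None = None
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    seed: int = 0

    def effective_thresholds(self) -> dict:
        out = dict(DEFAULT_THRESHOLDS)
        out.update(self.thresholds)
        return out


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(
        {k: (asdict(v) if isinstance(v, SimulationConfig) else v) for k, v in asdict(cfg).items()},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns (and writes) the consolidated report."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = cfg.effective_thresholds()
    report: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "thresholds": {k: {"effective": v, "default": DEFAULT_THRESHOLDS[k]} for k, v in th.items()},
    }

    if cfg.simulate is not None:
        sim = simulate_pair(cfg.simulate)
        sim.write(out / "sim")
        genomes = {"A": sim.genome_a, "B": sim.genome_b}
        library = sim.library
        genes_a = sim.genes_a
        centromeres_a = sim.centromere_bed("A")
        report["simulation"] = {"n_truth_elements": int(len(sim.truth))}
    else:
        if not (cfg.genome_a and cfg.genome_b and cfg.library):
            raise ValueError("run_all needs either a simulation config or genome/library paths")
        genomes = {"A": ckio.read_fasta(cfg.genome_a), "B": ckio.read_fasta(cfg.genome_b)}
        library = ckio.read_fasta(cfg.library)
        genes_a = cfg.genes_a
        centromeres_a = None
        if cfg.centromeres_a:
            bed = ckio.read_bed(cfg.centromeres_a)
            centromeres_a = list(bed[["chrom", "start", "end"]].itertuples(index=False, name=None))

    dcfg = DiscoveryConfig(min_score=th["min_score"], min_hit_len=th["min_hit_len"])
    ann = {}
    for g, genome in genomes.items():
        res = annotate(genome, library, dcfg, genome_id=g)
        ann[g] = res
        ckio.write_tsv(out / f"elements_{g}.tsv", res.to_dataframe())
        ckio.write_gff3(out / f"elements_{g}.gff3", res.to_gff3_features())
        report[f"discovery_{g}"] = res.summary
    complete = {g: [e for e in ann[g].elements if e.complete] for g in genomes}

    contexts, dropped = extract_site_context(complete["A"], genomes["A"], flank=th["profile_flank"])
    pfm = build_pfm(contexts, flank=th["profile_flank"])
    ckio.write_tsv(out / "pfm_full.tsv", pfm.to_dataframe())
    ckio.write_tsv(out / "pfm_logo.tsv", build_pfm(contexts, "logo", th["profile_flank"]).to_dataframe())
    genome_gc = gc_fraction("".join(genomes["A"].values()))
    bias = site_bias_report(pfm, genome_gc)
    report["insertion_profile"] = {**bias.as_dict(), "n_contexts": len(contexts), "n_edge_dropped": dropped}

    track = window_counts(ann["A"].elements, genomes["A"], th["window_size"], centromeres_a)
    ckio.write_tsv(out / "density_A.tsv", track.windows)
    report["distribution"] = {"per_chrom_density": track.per_chrom_density}
    if centromeres_a:
        regions = track.windows.region.value_counts()
        if regions.get("centromeric", 0) >= 2 and regions.get("arm", 0) >= 2:
            report["distribution"]["centromere_vs_arm"] = asdict(region_compare(track))
        else:
            logger.warning("too few windows for a centromere-vs-arm comparison; skipped")

    report["clustering"] = {}
    assignments = {}
    for g in genomes:
        assign = cluster_greedy(complete[g], th["id_thresh"], th["cov_thresh"])
        assignments[g] = assign
        summary = subfamily_summary(assign)
        ckio.write_tsv(out / f"subfamilies_{g}.tsv", summary)
        report["clustering"][g] = {
            "n_subfamilies": len(assign),
            "n_singletons": singleton_count(assign),
            "top_sizes": [a.size for a in assign[:5]],
        }

    indexes = {g: {c: KmerIndex(s) for c, s in genomes[g].items()} for g in genomes}
    fam = {g: [(e.chrom, e.start, e.end) for e in ann[g].elements] for g in genomes}
    calls = {}
    for src, tgt in (("A", "B"), ("B", "A")):
        calls[src] = call_polymorphisms(
            complete[src], genomes[src], genomes[tgt], fam[tgt],
            flank=th["polymorph_flank"], gap_max=th["gap_max"], indexes=indexes[tgt],
        )
        df = calls_to_dataframe(calls[src])
        ckio.write_tsv(out / f"polymorphism_calls_{src}_vs_{tgt}.tsv", df)
        n_abs = int((df.verdict == "absent").sum())
        size_mb = sum(len(s) for s in genomes[src].values()) / 1e6
        report[f"polymorphism_{src}_vs_{tgt}"] = {
            "verdicts": df.verdict.value_counts().to_dict(),
            "n_polymorphic": n_abs,
            "polymorphic_density_per_mb": polymorphic_density(n_abs, size_mb),
        }

    pairs, pair_report = pair_orthologs(calls["A"], calls["B"], complete["A"], complete["B"])
    cal = calibrate_rate(pairs, th["t_split"]) if pairs else None
    pairs_df = pd.DataFrame(
        [dict(a_id=p.a_id, b_id=p.b_id, k=p.distance.k, sites=p.distance.sites_compared) for p in pairs]
    )
    ckio.write_tsv(out / "ortholog_pairs.tsv", pairs_df)
    report["dating"] = {"pairing": pair_report}
    if cal is not None:
        report["dating"]["calibration"] = asdict(cal)
        (out / "calibration.json").write_text(json.dumps(asdict(cal), indent=2))
    top = assignments["A"][0]
    if top.size >= 2:
        seq_by_id = {e.element_id: e.oriented_seq() for e in complete["A"]}
        prof = divergence_profile([seq_by_id[m] for m in top.members])
        report["dating"]["top_subfamily_divergence_mode"] = list(prof.mode_bin)
    reps = [(a.label, a.representative) for a in assignments["A"][:20] if a.size >= 1]
    if len(reps) >= 3:
        seq_by_id = {e.element_id: e.oriented_seq() for e in complete["A"]}
        from .seqcore import kimura2p
        import numpy as np
        n = len(reps)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = kimura2p(seq_by_id[reps[i][1]], seq_by_id[reps[j][1]])
                mat[i, j] = mat[j, i] = d.k if not d.saturated else 1.0
        tree = nj_tree(mat, [lab for lab, _ in reps])
        (out / "subfamily_tree_A.nwk").write_text(tree.newick + "\n")
        report["dating"]["subfamily_tree_taxa"] = n

    if genes_a is not None:
        ctxs = classify_elements(ann["A"].elements, genes_a)
        ckio.write_tsv(out / "genic_contexts_A.tsv", contexts_to_dataframe(ctxs))
        report["genic_A"] = genic_summary(ctxs, ann["A"].elements)

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    logger.info("run complete: %s", out / "report.json")
    return report
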