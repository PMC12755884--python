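"""End-to-end orchestration: simulate/load -> core genes -> species
assignment -> diversity -> linkage -> hybrid classification -> sweeps ->
SNP blocks, with a JSON summary report.

Each stage writes its tabular output under the run directory and the report
aggregates the headline tallies (core genes, locus classes, transfers by
donor, troughs, sweep modes, blocks).  All randomness flows from one root
seed through per-stage derived seeds; stages with an existing primary output
are skipped (reloaded) unless ``force`` is set.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blocks as blocks_mod
from . import classify as classify_mod
from . import diversity as div_mod
from . import linkage as linkage_mod
from . import sweeps as sweeps_mod
from .io_core import (CellRecord, GeneAlignment, build_orthogroup_matrix,
                      call_core_genes, assign_cell_species,
                      consensus_sequence, read_cells_tsv,
                      read_gene_alignments, species_map, cells_of_species)
from .simulate import SimConfig, TruthTable, simulate_population, \
    write_simulation

log = logging.getLogger("hybridtrace")


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults, plus input/output paths.

    Exactly one input mode is used: a ``sim`` block (forward simulation) or
    ``alignments_dir`` + ``cells_tsv`` (pre-computed gene alignments).
    """

    out_dir: str = "hybridtrace_run"
    seed: int = 0
    sim: SimConfig | None = None
    alignments_dir: str | None = None
    cells_tsv: str | None = None
    # stage parameters
    alpha_core: float = 1e-3
    d_split: float = 0.075
    d_c: float = 0.075
    min_cluster: int = 2
    mosaic_frac: float = 0.8
    f_cut: float = 0.05
    d_trough: float = 0.2
    min_trough_genes: int = 1
    soft_factor: float = 10.0
    min_snps: int = 3
    min_block_cells: int = 3
    min_joint: int = 10
    max_gap_bp: int = 300
    min_mac: int = 2
    focus_species: str = "alpha"
    partner_species: str = "beta"
    stages: tuple = ("core", "assign", "diversity", "linkage", "classify",
                     "sweeps", "blocks")
    force: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            if "sweep_spec" in sim:
                sim["sweep_spec"] = tuple(tuple(s) for s in sim["sweep_spec"])
            for key in ("n_cells_per_species", "completeness_range",
                        "transfer_freq_range", "subgene_len_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.sim = SimConfig(**sim)
        return cfg


def _stage_seed(root: int, stage: str) -> int:
    # zlib.crc32 is stable across processes, unlike the builtin hash()
    import zlib
    return int(np.random.default_rng([root, zlib.crc32(stage.encode())])
               .integers(0, 2 ** 31))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; returns the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "parameters": {
        k: v for k, v in asdict(cfg).items() if k not in ("sim",)}}

    # --- stage 0: data -----------------------------------------------------
    if cfg.sim is not None:
        sim_dir = out / "sim"
        if cfg.force or not (sim_dir / "cells.tsv").exists():
            alignments, cells, truth = simulate_population(cfg.sim)
            write_simulation(sim_dir, alignments, cells, truth, cfg.sim)
        else:
            alignments = read_gene_alignments(sim_dir / "alignments")
            cells = read_cells_tsv(sim_dir / "cells.tsv")
            truth = TruthTable.from_json(sim_dir / "truth.json")
        report["simulated"] = True
    elif cfg.alignments_dir and cfg.cells_tsv:
        alignments = read_gene_alignments(cfg.alignments_dir)
        cells = read_cells_tsv(cfg.cells_tsv)
        truth = None
        report["simulated"] = False
    else:
        raise ValueError("config needs either a sim block or "
                         "alignments_dir + cells_tsv")
    sp_of = species_map(cells)
    report["n_cells"] = len(cells)
    report["n_genes"] = len(alignments)
    log.info("loaded %d genes x %d cells", len(alignments), len(cells))

    matrix = build_orthogroup_matrix(alignments, cells)

    # --- core genes --------------------------------------------------------
    core = sorted(alignments)
    if "core" in cfg.stages:
        multi = [g for g, a in alignments.items() if a.duplicated_cells()]
        core = call_core_genes(matrix, cfg.alpha_core, multi)
        pd.DataFrame({"gene_id": core}).to_csv(
            out / "core_genes.tsv", sep="\t", index=False)
        report["n_core_genes"] = len(core)
    core_alns = {g: alignments[g] for g in core}

    # --- species assignment (self-consistency vs per-species consensus) ----
    if "assign" in cfg.stages:
        refs = {}
        for sp in sorted({c.species for c in cells}):
            members = cells_of_species(cells, sp)
            refs[sp] = {g: consensus_sequence(a, [c for c in a.cell_ids
                                                  if c in set(members)])
                        for g, a in core_alns.items()
                        if any(c in set(members) for c in a.cell_ids)}
        assignments = assign_cell_species(core_alns, refs, cfg.d_split)
        assignments.to_csv(out / "species_assignments.tsv", sep="\t")
        agree = float(np.mean([assignments.loc[c.cell_id, "species"]
                               == c.species
                               for c in cells
                               if c.cell_id in assignments.index]))
        report["species_assignment_agreement"] = agree

    focus_cells = cells_of_species(cells, cfg.focus_species)
    partner_cells = cells_of_species(cells, cfg.partner_species)

    # --- diversity ---------------------------------------------------------
    backbone_rate = float("nan")
    if "diversity" in cfg.stages:
        div = div_mod.gene_diversity_table(core_alns, focus_cells)
        labels = div_mod.partition_backbone_hybrid(div["f_p"], cfg.f_cut)
        div["class"] = labels
        div.to_csv(out / "gene_diversity.tsv", sep="\t")
        scored = div.dropna(subset=["f_p"])
        k = scored["k_poly"].to_numpy(dtype=int)
        fits = {}
        try:
            z = div_mod.fit_poisson_zero_class(k)
            fits["zero_class"] = {"lambda": z.lambda_hat, "chi2": z.chi2,
                                  "pvalue": z.pvalue}
        except ValueError:
            fits["zero_class"] = None
        m = div_mod.fit_poisson_mean(k)
        fits["mean"] = {"lambda": m.lambda_hat, "chi2": m.chi2,
                        "pvalue": m.pvalue}
        backbone = scored[labels.loc[scored.index] == "backbone"]
        backbone_rate = float(backbone["pi_S"].mean()) if len(backbone) \
            else float("nan")
        report["diversity"] = {
            "species": cfg.focus_species,
            "n_backbone": int((labels == "backbone").sum()),
            "n_hybrid": int((labels == "hybrid").sum()),
            "backbone_pi_s": backbone_rate,
            "median_pi_s": float(scored["pi_S"].median()),
            "poisson_fits": fits,
        }

    # --- linkage -----------------------------------------------------------
    if "linkage" in cfg.stages:
        seed = _stage_seed(cfg.seed, "linkage")
        curve = linkage_mod.linkage_decay_curve(
            core_alns, focus_cells, min_joint=cfg.min_joint,
            min_mac=cfg.min_mac, seed=seed)
        curve.control = linkage_mod.unlinked_control(
            core_alns, focus_cells, seed=seed + 1, min_joint=cfg.min_joint,
            min_mac=cfg.min_mac)
        tab = pd.DataFrame({
            "bin_lo": curve.bin_edges[:-1], "bin_hi": curve.bin_edges[1:],
            "sigma_d2": curve.sigma_d2, "n_pairs": curve.n_pairs})
        tab = tab[tab.n_pairs > 0]
        with open(out / "linkage_curve.tsv", "w") as fh:
            fh.write(f"# genome_wide={curve.genome_wide:.6g} "
                     f"control={curve.control:.6g}\n")
            tab.to_csv(fh, sep="\t", index=False)
        try:
            rho, diag = linkage_mod.fit_decay_model(curve)
        except ValueError:
            rho, diag = float("nan"), {}
        report["linkage"] = {
            "species": cfg.focus_species,
            "genome_wide_sigma_d2": curve.genome_wide,
            "control_sigma_d2": curve.control,
            "rho_per_bp": rho, **{f"fit_{k}": v for k, v in diag.items()},
        }

    # --- hybrid classification --------------------------------------------
    locus_classes: dict[str, classify_mod.LocusClass] = {}
    transfers: list[classify_mod.TransferEvent] = []
    if "classify" in cfg.stages:
        for g, aln in sorted(core_alns.items()):
            if aln.n_seqs < 4:
                continue
            cs = classify_mod.cluster_gene(aln, cfg.d_c, cfg.min_cluster)
            expected = classify_mod.expected_cluster_sizes(aln, cells)
            lc = classify_mod.classify_locus(cs, sp_of, expected,
                                             cfg.mosaic_frac)
            locus_classes[g] = lc
            if lc.locus_class == classify_mod.SIMPLE_HYBRID:
                for ev in classify_mod.infer_transfers(cs, sp_of, expected):
                    ev.frequency = classify_mod.hybrid_allele_frequency(
                        ev, matrix, sp_of)
                    transfers.append(ev)
        pd.DataFrame(
            [{"gene_id": g, "class": lc.locus_class,
              "flags": ";".join(lc.flags)} for g, lc in locus_classes.items()]
        ).to_csv(out / "locus_classes.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"gene_id": t.gene_id, "donor": t.donor,
              "recipient": t.recipient, "n_carriers": t.n_carriers,
              "frequency": t.frequency, "flags": ";".join(t.flags)}
             for t in transfers]
        ).to_csv(out / "transfers.tsv", sep="\t", index=False)
        by_class: dict[str, int] = {}
        for lc in locus_classes.values():
            by_class[lc.locus_class] = by_class.get(lc.locus_class, 0) + 1
        by_donor: dict[str, int] = {}
        for t in transfers:
            by_donor[t.donor] = by_donor.get(t.donor, 0) + 1
        report["classification"] = {"locus_classes": by_class,
                                    "n_transfers": len(transfers),
                                    "transfers_by_donor": by_donor}

    # --- sweeps ------------------------------------------------------------
    if "sweeps" in cfg.stages and focus_cells and partner_cells:
        profile = sweeps_mod.interspecies_divergence_profile(
            core_alns, sorted(core_alns), focus_cells, partner_cells)
        profile.table.to_csv(out / "divergence_profile.tsv", sep="\t",
                             index=False)
        troughs = sweeps_mod.detect_troughs(profile, cfg.d_trough,
                                            cfg.min_trough_genes)
        pd.DataFrame(
            [{"start_index": t.start_index, "end_index": t.end_index,
              "n_genes": t.n_genes, "gene_ids": ",".join(t.gene_ids)}
             for t in troughs]
        ).to_csv(out / "troughs.tsv", sep="\t", index=False)
        calls = []
        for ev in transfers:
            if ev.recipient != cfg.focus_species or ev.n_carriers < 2:
                continue
            call = sweeps_mod.classify_sweep_mode(
                core_alns[ev.gene_id], ev.carriers, backbone_rate,
                cfg.soft_factor)
            calls.append(call)
        for t in troughs:
            for g in t.gene_ids:
                call = sweeps_mod.classify_sweep_mode(
                    core_alns[g],
                    [c for c in core_alns[g].cell_ids
                     if sp_of.get(c) == cfg.focus_species],
                    backbone_rate, cfg.soft_factor)
                calls.append(call)
        pd.DataFrame(
            [{"gene_id": c.gene_id, "mode": c.mode,
              "pi_S_hybrid": c.pi_s_hybrid, "n_alleles": c.n_alleles,
              "reason": c.reason} for c in calls]
        ).to_csv(out / "sweep_calls.tsv", sep="\t", index=False)
        modes: dict[str, int] = {}
        for c in calls:
            modes[c.mode] = modes.get(c.mode, 0) + 1
        report["sweeps"] = {
            "n_troughs": len(troughs),
            "n_trough_genes": int(sum(t.n_genes for t in troughs)),
            "largest_trough": max((t.n_genes for t in troughs), default=0),
            "sweep_modes": modes,
        }

    # --- SNP blocks --------------------------------------------------------
    if "blocks" in cfg.stages and focus_cells:
        seed = _stage_seed(cfg.seed, "blocks")
        other_sp = sorted({c.species for c in cells}
                          - {cfg.focus_species})
        all_blocks = []
        for g, aln in sorted(core_alns.items()):
            tab = blocks_mod.biallelic_snp_table(aln, focus_cells,
                                                 cfg.min_mac)
            found = blocks_mod.find_snp_blocks(
                tab, cfg.min_snps, cfg.min_block_cells, cfg.min_joint,
                cfg.max_gap_bp)
            for b in found:
                blocks_mod.block_haplotype_consensus(
                    b, aln, {sp: cells_of_species(cells, sp)
                             for sp in other_sp})
            all_blocks.extend(found)
        rows = []
        for b in all_blocks:
            row = {"gene_id": b.gene_id, "start_bp": b.start,
                   "end_bp": b.end, "n_snps": b.n_snps,
                   "n_h1": len(b.cells_h1), "n_h2": len(b.cells_h2)}
            for sp, (d1, d2) in b.d_to_other.items():
                row[f"d_{sp}_h1"], row[f"d_{sp}_h2"] = d1, d2
            row["match_flag"] = any(
                min(d) == 0.0 for d in b.d_to_other.values())
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "snp_blocks.tsv", sep="\t",
                                  index=False)
        block_report = {"species": cfg.focus_species,
                        "n_blocks": len(all_blocks)}
        if all_blocks:
            block_report["median_span_bp"] = float(
                np.median([b.span_bp for b in all_blocks]))
            block_report["frac_matching_other_species"] = float(
                np.mean([any(min(d) == 0.0 for d in b.d_to_other.values())
                         for b in all_blocks])) if other_sp else None
        try:
            link = blocks_mod.inter_block_linkage(
                all_blocks, cfg.min_joint, seed=seed, same_gene=False)
            pd.DataFrame({"data_r2": link.data_r2}).to_csv(
                out / "block_linkage.tsv", sep="\t", index=False)
            block_report["mean_r2_data"] = link.mean_data
            block_report["mean_r2_control"] = link.mean_control
        except ValueError:
            block_report["mean_r2_data"] = None
        report["blocks"] = block_report

    (out / "report.json").write_text(json.dumps(report, indent=1,
                                                default=str))
    return report
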