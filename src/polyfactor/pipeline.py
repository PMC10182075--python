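"""End-to-end pipeline: simulate -> munge -> LDSC -> factor model -> factor
GWAS -> regions -> conditional decomposition -> colocalization -> MR.

Each stage writes its outputs under the configured output directory and
contributes to a run manifest (stage timings, seeds, digests of key
tables). Deterministic stages reproduce byte-identical outputs when rerun
with an identical configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import conditional as cond_mod
from . import factor_model as fm
from . import ldsc as ldsc_mod
from . import mr as mr_mod
from . import regions as reg_mod
from .config import PipelineConfig
from .factor_gwas import run_factor_gwas
from .mr import mr_for_coloc_hit
from .simdata import (LDPanel, TrueGenerativeModel, make_ld_panel,
                      polygenic_model, simulate_multitrait_sumstats,
                      simulate_qtl_sumstats)
from .sumstats import effective_sample_size, munge, write_sumstats


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False, float_format="%.10g").encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Synthetic-study construction from config
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    panel: LDPanel
    model: TrueGenerativeModel
    truth: pd.DataFrame
    tables: dict
    qtl_tables: dict          # name -> (spec dict, DataFrame)
    planted: list             # resolved planted-locus dicts (with rsid, pos)


def build_synthetic_study(cfg: PipelineConfig) -> SyntheticStudy:
    sim = cfg.simulate
    if not sim:
        raise StageError("simulate", "noconfig", "no synthetic study configured")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    n_blocks = sim["n_blocks"]
    if sim.get("rho") == "spread":
        lo, hi = sim.get("rho_range", [0.1, 0.8])
        rho = rng.uniform(lo, hi, size=n_blocks)
    else:
        rho = sim["rho"]
    panel = make_ld_panel(sim["n_ref"], n_blocks, sim["block_size"], rho,
                         seed=cfg.seed)

    traits = sim["traits"]
    factors = sim["factors"]
    k, q = len(traits), len(factors)
    Lam = np.zeros((k, q))
    for fj, fname in enumerate(factors):
        for t in sim["pattern"][fname]:
            Lam[traits.index(t), fj] = sim["loadings"][t]
    Phi = np.full((q, q), sim.get("factor_corr", 0.25))
    np.fill_diagonal(Phi, 1.0)
    theta = np.array([sim["residuals"][t] for t in traits])
    neff = np.array([effective_sample_size(sim["cohorts"][t]) for t in traits])
    frac = np.eye(k)
    pcorr = np.eye(k)
    for a, b, f, r in sim.get("overlap", []):
        ia, ib = traits.index(a), traits.index(b)
        frac[ia, ib] = frac[ib, ia] = f
        pcorr[ia, ib] = pcorr[ib, ia] = r
    model = polygenic_model(panel, Lam, Phi, theta, neff, traits, factors,
                            seed=cfg.seed, overlap_frac=frac,
                            overlap_pheno_corr=pcorr)

    planted = []
    bs = sim["block_size"]
    for spec in sim.get("planted_loci", []):
        idx = spec["block"] * bs + spec["offset"]
        gamma = np.zeros(q)
        delta = np.zeros(k)
        if "gamma" in spec:
            for fname in spec["factors"]:
                gamma[factors.index(fname)] = spec["gamma"]
        if "delta" in spec:
            delta[traits.index(spec["trait"])] = spec["delta"]
        model.plant_variant(idx, gamma=gamma, delta=delta)
        resolved = dict(spec)
        resolved["index"] = idx
        resolved["rsid"] = str(panel.rsids[idx])
        resolved["chrom"] = int(panel.chrom[idx])
        resolved["pos"] = int(panel.positions[idx])
        resolved["label"] = str(model.labels[idx])
        planted.append(resolved)

    tables, truth = simulate_multitrait_sumstats(panel, model, seed=cfg.seed)

    qtl_tables = {}
    for i, qspec in enumerate(sim.get("qtls", [])):
        idx = qspec["block"] * bs + qspec["offset"]
        rsid = str(panel.rsids[idx])
        tab = simulate_qtl_sumstats(panel, rsid, qspec["effect"],
                                    qspec["n"], seed=cfg.seed + 1000 + i)
        resolved = dict(qspec)
        resolved["index"] = idx
        resolved["rsid"] = rsid
        qtl_tables[qspec["name"]] = (resolved, tab)

    return SyntheticStudy(panel=panel, model=model, truth=truth,
                          tables=tables, qtl_tables=qtl_tables,
                          planted=planted)


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: PipelineConfig
    manifest: dict = field(default_factory=dict)
    study: SyntheticStudy = None
    munged: dict = None
    scores: ldsc_mod.LDScores = None
    est: ldsc_mod.GeneticCovarianceEstimate = None
    groups: list = None
    fits: list = None
    selection: fm.ModelSelection = None
    factor_tables: dict = None
    merged_regions: list = None
    signal_sets: list = None
    coloc_results: list = None
    locus_groups: list = None
    qtl_hits: list = None
    qtl_results: list = None
    mr_results: list = None
    evaluation: dict = None

    @property
    def chosen_model(self) -> fm.FittedFactorModel:
        return self.selection.chosen


def _region_slice(table: pd.DataFrame, region, pad_bp: int) -> pd.DataFrame:
    lo, hi = region.start - pad_bp, region.end + pad_bp
    mask = (table["CHR"] == region.chrom) & (table["BP"] >= lo) & (table["BP"] <= hi)
    return table[mask].reset_index(drop=True)


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute every stage of the pipeline on the configured synthetic study."""
    cfg = config.validate()
    out = Path(cfg.outdir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    res = PipelineResult(config=cfg)
    manifest = {"seed": cfg.seed, "stages": {}}

    def stage(name):
        t0 = time.time()

        def done(**info):
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3),
                                        **info}
        return done

    # -- simulate ----------------------------------------------------------
    fin = stage("simulate")
    study = build_synthetic_study(cfg)
    res.study = study
    if write:
        study.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        study.panel.variant_table().to_csv(out / "reference.tsv", sep="\t",
                                           index=False)
    fin(n_variants=study.panel.m, n_traits=len(study.tables),
        truth_digest=_digest(study.truth))

    # -- munge -------------------------------------------------------------
    fin = stage("munge")
    reference = study.panel.variant_table()
    munged = {}
    for name, tab in study.tables.items():
        munged[name] = munge(tab, reference, maf_min=cfg.maf_min)
        if write:
            write_sumstats(munged[name], out / f"sumstats.{name}.tsv")
    res.munged = munged
    fin(n_kept={n: len(t) for n, t in munged.items()})

    # -- ldsc --------------------------------------------------------------
    fin = stage("ldsc")
    scores = ldsc_mod.compute_ld_scores(study.panel, window_kb=cfg.ld_window_kb)
    est = ldsc_mod.multivariable_ldsc(munged, scores,
                                      n_blocks=cfg.n_jackknife_blocks)
    res.scores, res.est = scores, est
    if write:
        est.save(str(out / "ldsc"))
    fin(h2=dict(zip(est.trait_names, np.round(np.diag(est.S), 4).tolist())))

    # -- factor model ------------------------------------------------------
    fin = stage("factor_model")
    res.groups = fm.propose_groups(est.rg(), threshold=cfg.rg_group,
                                   trait_names=est.trait_names)
    baseline = fm.fit_wls(est, fm.independence_spec(est.trait_names))
    fits = []
    for name, pattern in cfg.models.items():
        spec = fm.ModelSpec(factors={f: list(ts) for f, ts in pattern.items()},
                            trait_names=list(est.trait_names), name=name)
        fit = fm.fit_wls(est, spec)
        fm.fit_indices(fit, baseline)
        fits.append(fit)
    res.fits = fits
    res.selection = fm.select_model(fits, cfi_min=cfg.cfi_min,
                                    srmr_max=cfg.srmr_max,
                                    exclude=cfg.model_exclude)
    if res.selection.chosen is None:
        raise StageError("factor_model", "no_adequate_model",
                         "no candidate factor model passed the fit thresholds")
    if write:
        res.selection.report.to_csv(out / "model_selection.tsv", sep="\t",
                                    index=False)
        with open(out / "chosen_model.json", "w") as fh:
            json.dump(res.selection.chosen.to_dict(), fh, indent=2)
    fin(chosen=res.selection.chosen.spec.name,
        groups=[",".join(g) for g in res.groups])

    # -- factor GWAS -------------------------------------------------------
    fin = stage("factor_gwas")
    factor_tables = run_factor_gwas(munged, est, res.selection.chosen)
    res.factor_tables = factor_tables
    if write:
        for fname, tab in factor_tables.items():
            write_sumstats(tab, out / f"factor_gwas.{fname}.tsv")
    fin(digests={f: _digest(t) for f, t in factor_tables.items()})

    # -- regions -----------------------------------------------------------
    fin = stage("regions")
    per_factor = []
    for fname, tab in factor_tables.items():
        regs = reg_mod.define_regions(tab, trait=fname, p_seed=cfg.p_seed,
                                      gap_kb=cfg.gap_kb, p_sig=cfg.p_sig)
        if cfg.filter_before_merge:
            regs = [r for r in regs if r.significant]
        per_factor.append(regs)
    merged = reg_mod.merge_regions(per_factor)
    if not cfg.filter_before_merge:
        merged = [r for r in merged if r.significant]
    if cfg.exclude_hla:
        merged = reg_mod.exclude_hla(merged)
    res.merged_regions = merged
    if write:
        reg_mod.write_regions(merged, out / "regions.tsv")
    fin(n_regions=len(merged))

    # -- conditional decomposition ----------------------------------------
    fin = stage("conditional")
    pad_bp = int(cfg.region_pad_kb * 1000)
    signal_sets = []
    region_ld = {}
    for region in merged:
        any_tab = next(iter(factor_tables.values()))
        snps = _region_slice(any_tab, region, pad_bp)["SNP"].tolist()
        if not snps:
            continue
        ld = cond_mod.RegionLD.from_panel(study.panel, snps)
        region_ld[region.region_id] = ld
        for fname in sorted(region.traits):
            sl = _region_slice(factor_tables[fname], region, pad_bp)
            sig = cond_mod.decompose_region(sl, ld, trait=fname,
                                            region_id=region.region_id,
                                            p_stop=cfg.p_stop,
                                            p_cond=cfg.p_cond,
                                            p_orig=cfg.p_sig)
            if sig.selected:
                signal_sets.append(sig)
    res.signal_sets = signal_sets
    fin(n_signal_sets=len(signal_sets),
        n_signals=sum(len(s.valid_datasets()) for s in signal_sets))

    # -- colocalization across factors ------------------------------------
    fin = stage("coloc")
    results = []
    by_region = {}
    for s in signal_sets:
        by_region.setdefault(s.region_id, []).append(s)
    for rid, sets in by_region.items():
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                a, b = sets[i], sets[j]
                if a.trait == b.trait:
                    continue
                for da in a.valid_datasets():
                    for db in b.valid_datasets():
                        results.append(coloc_mod.coloc_pair(
                            da, db, p1=cfg.coloc_p1, p2=cfg.coloc_p2,
                            p12=cfg.coloc_p12,
                            prior_sd_a=cfg.prior_sd_gwas,
                            prior_sd_b=cfg.prior_sd_gwas,
                            min_overlap=cfg.min_overlap,
                            labels=(a.trait, da.target, b.trait, db.target)))
    groups = coloc_mod.group_signals(results, pp4_min=cfg.pp4_min)
    # signals never entering a tested pair are singleton loci
    grouped_nodes = {n for g in groups for n in g.members}
    next_id = len(groups)
    for s in signal_sets:
        for d in s.valid_datasets():
            node = (s.trait, d.target)
            if node not in grouped_nodes:
                groups.append(coloc_mod.LocusGroup(
                    members=frozenset([node]), label="specific",
                    group_id=next_id))
                next_id += 1
    res.coloc_results = results
    res.locus_groups = groups
    if write and results:
        coloc_mod.results_frame(results, groups).to_csv(
            out / "coloc.tsv", sep="\t", index=False)
    fin(n_pairs=len(results),
        n_shared_loci=sum(1 for g in groups if g.label == "shared"))

    # -- QTL colocalization + MR ------------------------------------------
    fin = stage("qtl")
    qtl_results, qtl_hits, mr_results = [], [], []
    for qname, (qspec, qtab) in study.qtl_tables.items():
        # locate the merged region containing the QTL's causal position
        pos = int(study.panel.positions[qspec["index"]])
        chrom = int(study.panel.chrom[qspec["index"]])
        hit_region = None
        for region in merged:
            if (region.chrom == chrom
                    and region.start - pad_bp <= pos <= region.end + pad_bp):
                hit_region = region
                break
        if hit_region is None:
            continue
        ld = region_ld[hit_region.region_id]
        sets = by_region.get(hit_region.region_id, [])
        out_q = coloc_mod.qtl_coloc(
            sets, qtab, ld, mode=qspec.get("mode", "decomposed"),
            qtl_name=qname, pp4_min=cfg.pp4_min, p1=cfg.coloc_p1,
            p2=cfg.coloc_p2, p12=cfg.coloc_p12,
            prior_sd_gwas=cfg.prior_sd_gwas, prior_sd_qtl=cfg.prior_sd_qtl,
            min_overlap=cfg.min_overlap)
        qtl_results.extend(out_q.results)
        qtl_hits.extend(out_q.hits)
        for hit in out_q.hits:
            exp_data = out_q.qtl_datasets[hit.signal_b]
            outcome_data = None
            for s in sets:
                if s.trait != hit.trait_a:
                    continue
                for d in s.valid_datasets():
                    if d.target == hit.signal_a:
                        outcome_data = d
            if outcome_data is None:
                continue
            try:
                mr_results.append(mr_for_coloc_hit(
                    exp_data, outcome_data, exposure=qname,
                    outcome=hit.trait_a,
                    cell_type=qspec.get("cell_type", "")))
            except (ValueError, mr_mod.WeakInstrumentError):
                continue
    res.qtl_results = qtl_results
    res.qtl_hits = qtl_hits
    res.mr_results = mr_results
    if write and qtl_results:
        coloc_mod.results_frame(qtl_results).to_csv(out / "qtl_coloc.tsv",
                                                    sep="\t", index=False)
    if write and mr_results:
        mr_mod.mr_frame(mr_results).to_csv(out / "mr.tsv", sep="\t",
                                           index=False)
    fin(n_qtl_pairs=len(qtl_results), n_qtl_hits=len(qtl_hits),
        n_mr=len(mr_results))

    # -- evaluation against planted truth ---------------------------------
    fin = stage("evaluate")
    res.evaluation = evaluate_against_truth(res)
    if write:
        with open(out / "evaluation.json", "w") as fh:
            json.dump(res.evaluation, fh, indent=2)
    fin(accuracy=res.evaluation["accuracy"])

    res.manifest = manifest
    if write:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return res


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------

def evaluate_against_truth(res: PipelineResult,
                           match_bp: int = 50_000) -> dict:
    """Score the pipeline's calls against the planted truth.

    Three classification tasks are pooled into one accuracy: (1) each
    planted factor locus must be recovered and labelled specific vs shared;
    (2) each planted QTL must be called colocalizing iff its causal variant
    is shared with a planted GWAS variant; (3) each truly colocalizing QTL
    with a significant MR result must carry the true direction of effect.
    """
    study = res.study
    pos_of = {str(s): (int(c), int(p)) for s, c, p in
              zip(study.panel.rsids, study.panel.chrom, study.panel.positions)}

    node_group = {}
    for g in res.locus_groups or []:
        for node in g.members:
            node_group[node] = g

    def signals_near(chrom, pos):
        hits = []
        for s in res.signal_sets or []:
            for d in s.valid_datasets():
                c, p = pos_of[d.target]
                if c == chrom and abs(p - pos) <= match_bp:
                    hits.append((s.trait, d.target))
        return hits

    tasks = []
    locus_calls = []
    for locus in study.planted:
        if locus["label"] not in ("specific", "shared"):
            continue
        near = signals_near(locus["chrom"], locus["pos"])
        if not near:
            predicted = "undetected"
        else:
            shared = any(node_group.get(n) is not None
                         and node_group[n].label == "shared" for n in near)
            predicted = "shared" if shared else "specific"
        correct = predicted == locus["label"]
        tasks.append(correct)
        locus_calls.append({"rsid": locus["rsid"], "truth": locus["label"],
                            "predicted": predicted, "correct": correct})

    qtl_calls = []
    planted_rsids = {p["rsid"] for p in study.planted
                     if p["label"] in ("specific", "shared")}
    hits_by_qtl = {}
    for h in res.qtl_hits or []:
        hits_by_qtl.setdefault(h.trait_b, []).append(h)
    mr_by_exposure = {}
    for m in res.mr_results or []:
        mr_by_exposure.setdefault(m.exposure, []).append(m)
    for qname, (qspec, _) in study.qtl_tables.items():
        truth_coloc = qspec["rsid"] in planted_rsids
        predicted_coloc = bool(hits_by_qtl.get(qname))
        tasks.append(predicted_coloc == truth_coloc)
        call = {"qtl": qname, "truth_coloc": truth_coloc,
                "predicted_coloc": predicted_coloc,
                "correct": predicted_coloc == truth_coloc}
        if truth_coloc:
            idx = qspec["index"]
            locus = next(p for p in study.planted if p["rsid"] == qspec["rsid"])
            fac_names = res.study.model.factor_names
            gdir = np.sign(sum(
                res.study.model.snp_factor_effects[idx][fac_names.index(f)]
                for f in locus.get("factors", [])))
            truth_dir = ("predisposing"
                         if gdir * np.sign(qspec["effect"]) > 0
                         else "protective")
            mrs = [m for m in mr_by_exposure.get(qname, [])
                   if m.p < res.config.mr_alpha]
            if mrs:
                best = min(mrs, key=lambda m: m.p)
                ok = best.direction == truth_dir
            else:
                ok = False
            tasks.append(ok)
            call["truth_direction"] = truth_dir
            call["mr_correct"] = ok
        qtl_calls.append(call)

    qsnp_detect = []
    for locus in study.planted:
        if locus["label"] != "heterogeneous":
            continue
        detected = False
        for tab in (res.factor_tables or {}).values():
            row = tab[tab["SNP"] == locus["rsid"]]
            if len(row) and float(row["QSNP_P"].iloc[0]) < 5e-8:
                detected = True
            break   # Q_SNP columns identical across factor tables
        qsnp_detect.append({"rsid": locus["rsid"], "detected": detected})

    accuracy = float(np.mean(tasks)) if tasks else np.nan
    return {"accuracy": accuracy, "n_tasks": len(tasks),
            "locus_calls": locus_calls, "qtl_calls": qtl_calls,
            "qsnp_detection": qsnp_detect,
            "n_regions": len(res.merged_regions or []),
            "n_signals": sum(len(s.valid_datasets())
                             for s in res.signal_sets or [])}
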