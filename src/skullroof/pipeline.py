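"""Dataset loading, the end-to-end analysis pipeline, and report writing.

A study bundle holds the tree, the per-section specimen table, the binary
section masks, the lifestyle classification and the run configuration.  The
pipeline sequences the full analysis: mask morphometry -> per-taxon trait
vectors -> phylogenetic ANOVA per trait -> Pagel's-lambda signal ->
stochastic mapping of the binarised lifestyle with branch posteriors and
acquisition calls -> Retention Index and phylogeny-lifestyle PLS -> C1/C5
convergence indices with BM-simulation p-values -> PCA.  Every stage is
deterministic given the configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometry as mm
from . import phylo_stats as ps
from .convergence import (FocalSet, c1_pvalue, c5_bivariate, c5_pvalue,
                          mean_convergence_vectors, _node_values)
from .phylogeny import (Tree, branch_posterior, fit_lambda_ml, fit_mk,
                        read_newick, prune_tree, retention_index,
                        simmap_sample)

log = logging.getLogger("skullroof")

TRAITS = ("c", "d", "ovl", "rfp", "elo", "dia")

DEFAULT_CONFIG = {
    "seed": 0,
    "n_perm": 10_000,       # RRPP permutations
    "n_sim": 30_000,        # BM simulations behind C1/C5 p-values
    "n_maps": 10_000,       # stochastic character maps
    "traits": list(TRAITS),
    "pca_traits": ["c", "dia", "elo", "rfp"],
    "boundary": "extrapolate",
    "focal_threshold": 0.5,
    "mk_flavour": "ER",
    "root_prior": "stationary",
}


@dataclass
class StudyBundle:
    tree: Tree
    specimens: pd.DataFrame
    lifestyle: pd.Series
    masks: dict[tuple[str, str, int], np.ndarray] | None
    config: dict
    traits: pd.DataFrame | None = None
    aux_traits: pd.DataFrame | None = None
    focal_clades: list[frozenset[str]] | None = None
    warnings: list[str] = field(default_factory=list)


class SchemaError(ValueError):
    pass


_SPECIMEN_COLS = ["taxon", "bone", "section_index", "s_position",
                  "bone_length_mm", "l_cran", "w_cran", "h_cran",
                  "pixel_size_mm"]


def load_dataset(path, config: dict | None = None,
                 load_masks: bool = True) -> StudyBundle:
    """Load and validate a study directory (tree.nwk, specimens.csv,
    lifestyle.csv, masks/, optional traits.csv and focal_clades.csv)."""
    root = Path(path)
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    if cfg.get("seed") is None:
        raise SchemaError("config seed is mandatory")
    tree = read_newick(root / "tree.nwk")

    spec_path = root / "specimens.csv"
    specimens = None
    if spec_path.exists():
        specimens = pd.read_csv(spec_path)
        missing = [c for c in _SPECIMEN_COLS if c not in specimens.columns]
        if missing:
            raise SchemaError(f"{spec_path.name}: missing columns {missing}")
        bad = specimens[~specimens["bone"].isin(mm.BONES)]
        if len(bad):
            raise SchemaError(
                f"{spec_path.name}: unknown bone at rows {bad.index.tolist()}")
        bad = specimens[~specimens["section_index"].isin([1, 2])]
        if len(bad):
            raise SchemaError(
                f"{spec_path.name}: bad section_index at rows {bad.index.tolist()}")

    ls = pd.read_csv(root / "lifestyle.csv")
    if "taxon" not in ls.columns or "lifestyle" not in ls.columns:
        raise SchemaError("lifestyle.csv must have columns taxon, lifestyle")
    lifestyle = ls.set_index("taxon")["lifestyle"]

    traits = None
    if (root / "traits.csv").exists():
        traits = pd.read_csv(root / "traits.csv").set_index("taxon")
    # generator-written reference traits: source of any purely simulated
    # columns (e.g. the neutral control trait) that masks cannot encode
    aux = None
    if (root / "traits_true.csv").exists():
        aux = pd.read_csv(root / "traits_true.csv").set_index("taxon")

    focal = None
    if (root / "focal_clades.csv").exists():
        fc = pd.read_csv(root / "focal_clades.csv")
        focal = [frozenset(g["taxon"]) for _, g in fc.groupby("clade_id")]

    warnings_: list[str] = []
    tipset = set(tree.tip_labels)
    table_taxa = set(lifestyle.index)
    if specimens is not None:
        table_taxa |= set(specimens["taxon"])
    unmatched = sorted(table_taxa - tipset)
    if unmatched:
        warnings_.append(f"taxa absent from tree: {unmatched}")
    extra = sorted(tipset - set(lifestyle.index))
    if extra:
        warnings_.append(f"tree tips without lifestyle: {extra}")

    masks = None
    if load_masks and specimens is not None and (root / "masks").is_dir():
        from PIL import Image

        masks = {}
        for _, row in specimens.iterrows():
            f = root / "masks" / row["mask_file"]
            if not f.exists():
                warnings_.append(f"missing mask file {f.name}")
                continue
            arr = np.asarray(Image.open(f))
            masks[(row["taxon"], row["bone"], int(row["section_index"]))] = arr > 0

    for w in warnings_:
        log.warning(w)
    return StudyBundle(tree=tree, specimens=specimens, lifestyle=lifestyle,
                       masks=masks, config=cfg, traits=traits, aux_traits=aux,
                       focal_clades=focal, warnings=warnings_)


# -- stage: morphometry ---------------------------------------------------


def measure_traits(bundle: StudyBundle) -> pd.DataFrame:
    """Per-taxon trait vectors from the masks and specimen table."""
    if bundle.specimens is None or bundle.masks is None:
        raise ValueError("bundle has no masks; supply traits.csv instead")
    rows = []
    for taxon, g in bundle.specimens.groupby("taxon"):
        spans: dict[str, mm.BoneSpan] = {}
        for bone, gb in g.groupby("bone"):
            s = gb.set_index("section_index")["s_position"]
            spans[bone] = mm.BoneSpan(bone=bone,
                                      length_mm=float(gb["bone_length_mm"].iloc[0]),
                                      s1=float(s[1]), s2=float(s[2]))
        first = g.iloc[0]
        dims = mm.SkullDimensions(l_cran=float(first["l_cran"]),
                                  w_cran=float(first["w_cran"]),
                                  h_cran=float(first["h_cran"]))
        px = float(first["pixel_size_mm"])
        masks = {}
        for _, row in g.iterrows():
            key = (taxon, row["bone"], int(row["section_index"]))
            if bundle.masks.get(key) is not None:
                masks[(row["bone"], int(row["section_index"]))] = mm.SectionMask(
                    bundle.masks[key], px, row["bone"], int(row["section_index"]))
        total = float(first["l_cran"])  # profile length proxy
        profile = mm.CranialProfile(landmarks=np.zeros((2, 2)),
                                    s=np.array([0.0, 1.0]),
                                    total_length=total)
        tv = mm.specimen_traits(
            taxon, masks, profile, spans, dims,
            lifestyle=str(bundle.lifestyle.get(taxon, "unknown")),
            boundary=bundle.config.get("boundary", "extrapolate"),
        )
        rows.append({"taxon": tv.taxon, "c": tv.c, "d": tv.d, "ovl": tv.ovl,
                     "rfp": tv.rfp, "elo": tv.elo, "dia": tv.dia,
                     "c_log": tv.c_log, "lifestyle": tv.lifestyle,
                     "n_missing": len(tv.missing)})
    return pd.DataFrame(rows).set_index("taxon")


# -- full pipeline --------------------------------------------------------


def run_full_pipeline(bundle: StudyBundle) -> dict:
    """Run every analysis stage; returns a results dict (see write_report)."""
    cfg = bundle.config
    seed = int(cfg["seed"])
    results: dict = {"config": dict(cfg), "stages": []}

    def stage(name):
        log.info("stage: %s", name)
        results["stages"].append(name)

    if bundle.traits is not None:
        traits = bundle.traits.copy()
        stage("traits:provided")
    else:
        stage("measure")
        traits = measure_traits(bundle)
        if bundle.aux_traits is not None:
            extra = [c for c in bundle.aux_traits.columns
                     if c not in traits.columns]
            traits = traits.join(bundle.aux_traits[extra])
    # restrict to taxa on the tree
    on_tree = [t for t in traits.index if t in set(bundle.tree.tip_labels)]
    traits = traits.loc[on_tree]
    tree = prune_tree(bundle.tree, on_tree) if len(on_tree) < bundle.tree.n_tips \
        else bundle.tree
    if "lifestyle" not in traits.columns:
        traits["lifestyle"] = bundle.lifestyle.reindex(traits.index)
    results["traits"] = traits
    results["tree"] = tree

    trait_names = [t for t in cfg["traits"] if t in traits.columns]
    lifestyle = traits["lifestyle"]

    stage("anova")
    anova = {}
    for name in trait_names:
        anova[name] = ps.phylo_anova_rrpp(
            traits[name], lifestyle, tree,
            n_perm=int(cfg["n_perm"]), seed=seed)
    results["anova"] = anova

    stage("signal")
    signal = {name: fit_lambda_ml(tree, traits[name]) for name in trait_names}
    results["lambda"] = signal

    stage("ancmap")
    binary = lifestyle.map(lambda s: "fully" if s == "fully" else "other")
    mk = fit_mk(tree, binary, flavour=cfg["mk_flavour"],
                root_prior=cfg["root_prior"])
    maps = simmap_sample(tree, binary, mk, n_maps=int(cfg["n_maps"]),
                         seed=seed + 1, root_prior=cfg["root_prior"])
    profiles, acquisitions = branch_posterior(
        tree, maps, "fully", threshold=float(cfg["focal_threshold"]))
    results["mk"] = mk
    results["branch_posterior"] = profiles
    results["acquisitions"] = acquisitions
    results["ri"] = retention_index(tree, binary)
    results["pls"] = ps.phylo_pls_lifestyle(
        tree, lifestyle, n_perm=min(int(cfg["n_perm"]), 1000), seed=seed + 2)

    stage("converge")
    if bundle.focal_clades:
        focal = FocalSet(bundle.focal_clades)
    else:
        # derive focal clades from the >50% acquisition branches
        focal = _focal_from_acquisitions(tree, acquisitions, binary)
    results["focal"] = focal
    conv = {}
    for name in trait_names + (["control"] if "control" in traits.columns else []):
        c1 = c1_pvalue(tree, traits[name], focal,
                       n_sim=int(cfg["n_sim"]), seed=seed + 3)
        c5 = c5_pvalue(tree, traits[name], focal,
                       n_sim=int(cfg["n_sim"]), seed=seed + 3)
        conv[name] = {"C1": c1, "C5": c5}
    results["convergence"] = conv

    stage("pca")
    pca_cols = [t for t in cfg["pca_traits"] if t in traits.columns]
    results["pca"] = ps.pca_traits(traits[pca_cols])
    return results


def _focal_from_acquisitions(tree: Tree, acquisitions: list[int],
                             binary: pd.Series) -> FocalSet:
    """Focal clades = fully tips grouped under each acquisition branch."""
    clades = []
    claimed: set[str] = set()
    # deeper acquisitions first so nested ones refine, not duplicate
    for u in sorted(acquisitions, key=lambda u: tree.node_depths[u]):
        tips = _tips_below(tree, u)
        members = {t for t in tips
                   if binary.get(t) == "fully" and t not in claimed}
        if members:
            clades.append(frozenset(members))
            claimed |= members
    if len(clades) < 2:
        # fall back: each fully tip not claimed forms its own lineage
        rest = [t for t in tree.tip_labels
                if binary.get(t) == "fully" and t not in claimed]
        clades.extend(frozenset({t}) for t in rest)
    return FocalSet([c for c in clades if c])


def _tips_below(tree: Tree, node: int) -> list[str]:
    out, stack = [], [node]
    while stack:
        u = stack.pop()
        if u < tree.n_tips:
            out.append(tree.tip_labels[u])
        else:
            stack.extend(tree.children[u])
    return out


# -- reporting ------------------------------------------------------------


def results_summary(results: dict) -> dict:
    """Flatten the results into a JSON-serialisable summary."""
    summ: dict = {"stages": results["stages"], "config": results["config"]}
    if "anova" in results:
        summ["anova"] = {
            k: {"F": r.F, "p": r.p, "lambda": r.lambda_used,
                "pairwise": r.pairwise.to_dict("records") if r.pairwise is not None else None}
            for k, r in results["anova"].items()}
    if "lambda" in results:
        summ["lambda"] = {k: {"lambda": v.lam, "logL": v.logL,
                              "clamped": v.clamped}
                          for k, v in results["lambda"].items()}
    if "ri" in results:
        summ["ri"] = results["ri"]
    if "pls" in results:
        summ["r_pls"] = results["pls"].r_pls
        summ["p_pls"] = results["pls"].p
    if "acquisitions" in results:
        summ["n_acquisitions"] = len(results["acquisitions"])
    if "convergence" in results:
        summ["convergence"] = {
            k: {"C1": v["C1"].C1, "p_C1": v["C1"].p,
                "C5": v["C5"].C5, "p_C5": v["C5"].p}
            for k, v in results["convergence"].items()}
    if "pca" in results:
        summ["pca_variance_fractions"] = \
            results["pca"].variance_fractions.tolist()
    if "focal" in results:
        summ["focal_clades"] = [sorted(c) for c in results["focal"].clades]
    return summ


def write_report(results: dict, outdir, plots: bool = False) -> list[Path]:
    """Write CSV tables, a JSON summary, and (optionally) figures."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        p = out / name
        df.to_csv(p, index=index)
        written.append(p)

    if "traits" in results:
        save(results["traits"], "traits.csv", index=True)
    if "anova" in results:
        rows, pw_rows = [], []
        for k, r in results["anova"].items():
            rows.append({"trait": k, "lambda": r.lambda_used, "F": r.F,
                         "p": r.p, "n_perm": r.n_permutations})
            if r.pairwise is not None:
                pw = r.pairwise.copy()
                pw.insert(0, "trait", k)
                pw_rows.append(pw)
        save(pd.DataFrame(rows), "anova.csv")
        if pw_rows:
            save(pd.concat(pw_rows, ignore_index=True), "anova_pairwise.csv")
    if "convergence" in results:
        rows = [{"trait": k, "C1": v["C1"].C1, "p_C1": v["C1"].p,
                 "C5": v["C5"].C5, "p_C5": v["C5"].p,
                 "n_sim": v["C1"].n_sim}
                for k, v in results["convergence"].items()]
        save(pd.DataFrame(rows), "convergence.csv")
    if "pca" in results:
        save(results["pca"].loadings, "pca_loadings.csv", index=True)
        save(results["pca"].scores, "pca_scores.csv", index=True)
    summary = results_summary(results)
    p = out / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    written.append(p)
    if plots:
        written.extend(_write_plots(results, out))
    return written


def _write_plots(results: dict, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    traits = results.get("traits")
    if traits is not None and {"c", "dia"} <= set(traits.columns) \
            and "focal" in results:
        # bivariate morphospace: focal ellipse, entering lineages, mean vector
        fig, ax = plt.subplots(figsize=(5, 4))
        for ls, g in traits.groupby("lifestyle"):
            ax.scatter(g["c"], g["dia"], label=str(ls), s=12)
        tree = results.get("tree")
        try:
            biv = c5_bivariate(tree, [traits["c"], traits["dia"]],
                               results["focal"]) if tree is not None else None
        except Exception:
            biv = None
        if biv is not None:
            c0 = np.array(biv.region["centre"])
            E = np.array(biv.region["shape"])
            evals, evecs = np.linalg.eigh(E)
            th = np.linspace(0, 2 * np.pi, 200)
            circ = np.column_stack([np.cos(th), np.sin(th)])
            ell = c0 + (circ / np.sqrt(evals)) @ evecs.T
            ax.plot(ell[:, 0], ell[:, 1], "k--", lw=1,
                    label=f"focal ellipse (C5={biv.C5})")
            if biv.entering:
                nodes = np.column_stack([_node_values(tree, traits["c"]),
                                         _node_values(tree, traits["dia"])])
                v = mean_convergence_vectors(tree, nodes, biv.entering)
                ax.annotate("", xy=c0 + v, xytext=c0,
                            arrowprops={"arrowstyle": "->", "color": "k"})
        ax.set_xlabel("compactness")
        ax.set_ylabel("dia [mm]")
        ax.legend(fontsize=7)
        p = out / "morphospace_c_dia.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    if "pca" in results:
        fig, ax = plt.subplots(figsize=(5, 4))
        sc = results["pca"].scores
        ax.scatter(sc.iloc[:, 0], sc.iloc[:, 1], s=12)
        vf = results["pca"].variance_fractions
        ax.set_xlabel(f"PC1 ({100 * vf[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * vf[1]:.1f}%)")
        p = out / "pca.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    return written


# -- external-data validation --------------------------------------------


def external_headline_stats(tree_path, traits_csv, lifestyle_csv,
                            focal_csv, trait: str = "c",
                            n_sim: int = 30_000, n_perm: int = 10_000,
                            seed: int = 0) -> dict:
    """Headline statistics on an externally supplied empirical dataset.

    Computes, from user-provided measurement and tree files, the univariate
    C1 and C5 (with BM-simulation p-values) for the chosen trait, the
    Retention Index of the binarised lifestyle, the phylogeny-lifestyle
    r-PLS, and the PC1 variance fraction of the converging-trait PCA under
    both covariance and correlation scaling.  Intended for validating the
    pipeline against an external empirical dataset once its measurements
    and calibrated tree are available; it makes no claim desk-side.
    """
    tree = read_newick(tree_path)
    traits = pd.read_csv(traits_csv).set_index("taxon")
    lifestyle = pd.read_csv(lifestyle_csv).set_index("taxon")["lifestyle"]
    fc = pd.read_csv(focal_csv)
    focal = FocalSet([frozenset(g["taxon"]) for _, g in fc.groupby("clade_id")])
    keep = [t for t in tree.tip_labels if t in traits.index]
    tree = prune_tree(tree, keep) if len(keep) < tree.n_tips else tree
    c1 = c1_pvalue(tree, traits[trait], focal, n_sim=n_sim, seed=seed)
    c5 = c5_pvalue(tree, traits[trait], focal, n_sim=n_sim, seed=seed)
    binary = lifestyle.map(lambda s: "fully" if s == "fully" else "other")
    ri = retention_index(tree, binary.loc[list(tree.tip_labels)])
    pls = ps.phylo_pls_lifestyle(tree, lifestyle.loc[list(tree.tip_labels)],
                                 n_perm=n_perm, seed=seed)
    pca_cols = [c for c in ("c", "dia", "elo", "rfp") if c in traits.columns]
    pc1_corr = ps.pca_traits(traits.loc[list(tree.tip_labels), pca_cols],
                             standardize=True).variance_fractions[0]
    pc1_cov = ps.pca_traits(traits.loc[list(tree.tip_labels), pca_cols],
                            standardize=False).variance_fractions[0]
    return {
        "C1": c1.C1, "p_C1": c1.p, "C5": c5.C5, "p_C5": c5.p,
        "RI": ri, "r_PLS": pls.r_pls, "p_PLS": pls.p,
        "PC1_fraction_correlation": float(pc1_corr),
        "PC1_fraction_covariance": float(pc1_cov),
    }
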