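"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a fossorial-convergence skull-roof
study so that every pipeline stage can be exercised and validated without
real scan data: a pure-birth ultrametric phylogeny (~99 tips), a 3-state
Mk lifestyle history (non / semi / fully fossorial, binarised where the
analyses require it), state-dependent Ornstein-Uhlenbeck trait evolution
with a high-compactness / small-diameter / elongate optimum in the fully
fossorial regime plus a neutral Brownian control trait, and procedurally
generated binary cross-section masks whose realised compactness and shell
thickness encode the per-tip trait values.

Every generated artifact carries its ground truth; downstream validation
reads truth from the generator's JSON, never from re-derivation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .morphometry import BONES
from .phylogeny import Tree, write_newick

LIFESTYLES = ("non", "semi", "fully")

__all__ = [
    "SimConfig",
    "OUSpec",
    "gen_tree",
    "gen_lifestyle",
    "gen_traits",
    "gen_section_masks",
    "gen_dataset",
    "fully_fossorial_clades",
    "LifestyleHistory",
    "DEFAULT_Q",
    "LIFESTYLES",
]

# lifestyle transition rates chosen to yield several independent fully
# fossorial origins on a ~99-tip pure-birth tree (total length ~n/birth_rate)
DEFAULT_Q = np.array([
    [-0.27, 0.25, 0.02],    # non  -> semi, fully
    [0.10, -0.30, 0.20],    # semi -> non, fully
    [0.005, 0.03, -0.035],  # fully -> non, semi
])


@dataclass
class OUSpec:
    """State-dependent OU parameters for one trait.

    theta maps lifestyle to its adaptive optimum; alpha is the pull
    strength (1/My), sigma the diffusion; clamping keeps physically bounded
    traits in range.  alpha = 0 degrades to Brownian motion.
    """

    theta: dict[str, float]
    alpha: float
    sigma: float
    root: float | None = None
    clamp: tuple[float, float] | None = None


def default_trait_specs() -> dict[str, OUSpec]:
    return {
        # compactness on the percent scale; fully fossorial optimum high
        "c": OUSpec(theta={"non": 55.0, "semi": 65.0, "fully": 96.0},
                    alpha=2.0, sigma=6.0, clamp=(40.0, 99.5)),
        # baseline relative thickness (% of dia) behind the d integral
        "d_rel_base": OUSpec(theta={"non": 2.0, "semi": 2.4, "fully": 3.5},
                             alpha=1.5, sigma=0.8, clamp=(0.5, 8.0)),
        "ovl": OUSpec(theta={"non": 15.0, "semi": 25.0, "fully": 45.0},
                      alpha=1.5, sigma=8.0, clamp=(-20.0, 62.0)),
        "rfp": OUSpec(theta={"non": 1.2, "semi": 1.0, "fully": 0.6},
                      alpha=1.5, sigma=0.15, clamp=(0.2, 2.5)),
        "elo": OUSpec(theta={"non": 2.0, "semi": 2.2, "fully": 2.9},
                      alpha=1.5, sigma=0.25, clamp=(1.2, 4.0)),
        "dia": OUSpec(theta={"non": 8.0, "semi": 6.0, "fully": 3.5},
                      alpha=1.0, sigma=1.0, clamp=(1.0, 15.0)),
        # neutral control trait: pure BM, no lifestyle dependence
        "control": OUSpec(theta={"non": 0.0, "semi": 0.0, "fully": 0.0},
                          alpha=0.0, sigma=1.0),
    }


@dataclass
class SimConfig:
    n_tips: int = 99
    birth_rate: float = 1.0
    Q: np.ndarray = field(default_factory=lambda: DEFAULT_Q.copy())
    root_state: str = "non"
    trait_specs: dict[str, OUSpec] = field(default_factory=default_trait_specs)
    mask_shape: tuple[int, int] = (48, 64)
    pixel_size_mm: float = 0.02
    section_noise_sd: float = 0.8  # percent compactness jitter per section
    min_fully_clades: int = 2
    min_clade_tips: int = 2
    min_class_tips: int = 2   # every lifestyle class represented >= this
    seed: int = 0

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if np.any(self.Q[~np.eye(3, dtype=bool)] < 0):
            raise ValueError("off-diagonal Mk rates must be non-negative")


# -- tree ----------------------------------------------------------------


def gen_tree(n_tips: int, birth_rate: float = 1.0,
             seed: int | np.random.Generator | None = None) -> Tree:
    """Pure-birth (Yule) ultrametric tree with n_tips extant tips."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # active lineages as (node_id, birth_time); build parent/length arrays
    parent: list[int] = [-1]
    birth: list[float] = [0.0]
    active = [0]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        u = active[k]
        c1, c2 = len(parent), len(parent) + 1
        parent.extend([u, u])
        birth.extend([t, t])
        active[k] = c1
        active.append(c2)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    n_total = len(parent)
    blen = np.zeros(n_total)
    is_tip = np.ones(n_total, dtype=bool)
    for i, p in enumerate(parent):
        if p >= 0:
            is_tip[p] = False
    child_birth = {i: [] for i in range(n_total)}
    for i, p in enumerate(parent):
        if p >= 0:
            child_birth[p].append(birth[i])
    for i in range(n_total):
        end = t if is_tip[i] else child_birth[i][0]
        blen[i] = end - birth[i]
    # remap: tips first
    tips = [i for i in range(n_total) if is_tip[i]]
    internals = [i for i in range(n_total) if not is_tip[i]]
    remap = {old: new for new, old in enumerate(tips + internals)}
    new_parent = np.full(n_total, -1, dtype=int)
    new_blen = np.zeros(n_total)
    for old in range(n_total):
        new_parent[remap[old]] = remap[parent[old]] if parent[old] >= 0 else -1
        new_blen[remap[old]] = blen[old]
    labels = [f"t{i + 1}" for i in range(len(tips))]
    return Tree(parent=new_parent, blen=new_blen, tip_labels=labels)


# -- lifestyle history ----------------------------------------------------


@dataclass
class LifestyleHistory:
    tip_states: pd.Series
    segments: dict[int, list[tuple[str, float]]]
    node_states: dict[int, str]
    n_transitions: int

    def transitions(self) -> list[tuple[int, str, str]]:
        out = []
        for u, segs in self.segments.items():
            for (s0, _), (s1, _) in zip(segs, segs[1:]):
                out.append((u, s0, s1))
        return out


def gen_lifestyle(tree: Tree, Q: np.ndarray,
                  seed: int | np.random.Generator | None = None,
                  root_state: str = "non") -> LifestyleHistory:
    """Simulate the 3-state Mk lifestyle process root-to-tips (Gillespie)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    sidx = {s: i for i, s in enumerate(LIFESTYLES[:k])}
    node_state = {tree.root: sidx[root_state]}
    segments: dict[int, list[tuple[str, float]]] = {}
    n_trans = 0
    for u in tree.preorder:
        if u == tree.root:
            continue
        s = node_state[tree.parent[u]]
        t_total = float(tree.blen[u])
        t_done = 0.0
        segs: list[tuple[str, float]] = []
        while True:
            rate = -Q[s, s]
            wait = rng.exponential(1.0 / rate) if rate > 0 else math.inf
            if t_done + wait >= t_total:
                segs.append((LIFESTYLES[s], t_total - t_done))
                break
            segs.append((LIFESTYLES[s], wait))
            t_done += wait
            probs = Q[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            s = int(rng.choice(k, p=probs))
            n_trans += 1
        segments[u] = segs
        node_state[u] = s
    tips = pd.Series({tree.tip_labels[i]: LIFESTYLES[node_state[i]]
                      for i in range(tree.n_tips)})
    return LifestyleHistory(
        tip_states=tips, segments=segments,
        node_states={u: LIFESTYLES[s] for u, s in node_state.items()},
        n_transitions=n_trans,
    )


def fully_fossorial_clades(tree: Tree, history: LifestyleHistory,
                           min_tips: int = 1) -> list[frozenset[str]]:
    """Independent fully-fossorial origins: maximal sets of 'fully' tips
    whose connecting path stayed 'fully' since a single acquisition."""
    # walk preorder; a clade starts where a branch history ends in 'fully'
    # but the parent node is not 'fully'
    clade_of: dict[int, int] = {}
    clades: list[set[str]] = []
    for u in tree.preorder:
        if u == tree.root:
            if history.node_states[u] == "fully":
                clades.append(set())
                clade_of[u] = len(clades) - 1
            continue
        p = tree.parent[u]
        if history.node_states[u] == "fully":
            parent_fully = p in clade_of
            stayed = all(s == "fully" for s, _ in history.segments[u])
            if parent_fully and stayed:
                clade_of[u] = clade_of[p]
            else:
                clades.append(set())
                clade_of[u] = len(clades) - 1
            if u < tree.n_tips:
                clades[clade_of[u]].add(tree.tip_labels[u])
    return [frozenset(c) for c in clades if len(c) >= min_tips]


# -- traits ---------------------------------------------------------------


def _ou_segment(x: float, spec: OUSpec, state: str, dt: float, rng) -> float:
    """Exact OU transition over one constant-regime segment."""
    if dt <= 0:
        return x
    a, s = spec.alpha, spec.sigma
    if a == 0:
        return x + rng.normal(0.0, s * math.sqrt(dt))
    th = spec.theta[state]
    decay = math.exp(-a * dt)
    var = s * s * (1.0 - decay * decay) / (2.0 * a)
    return th + (x - th) * decay + rng.normal(0.0, math.sqrt(var))


def gen_traits(tree: Tree, history: LifestyleHistory,
               specs: dict[str, OUSpec] | None = None,
               seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """State-switching OU trait evolution along the lifestyle history.

    Each branch is traversed segment by segment (regime = lifestyle state
    during that segment) using the exact OU transition density, so there is
    no discretisation error and alpha = 0 reduces exactly to BM.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    specs = specs if specs is not None else default_trait_specs()
    vals: dict[str, dict[int, float]] = {}
    for name, spec in specs.items():
        root_val = spec.root if spec.root is not None \
            else spec.theta[history.node_states[tree.root]]
        v = {tree.root: root_val}
        for u in tree.preorder:
            if u == tree.root:
                continue
            x = v[tree.parent[u]]
            for state, dur in history.segments[u]:
                x = _ou_segment(x, spec, state, dur, rng)
            v[u] = x
        vals[name] = v
    rows = {}
    for i, lab in enumerate(tree.tip_labels):
        row = {}
        for name, spec in specs.items():
            x = vals[name][i]
            if spec.clamp is not None:
                x = min(max(x, spec.clamp[0]), spec.clamp[1])
            row[name] = x
        rows[lab] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "taxon"
    df["lifestyle"] = history.tip_states
    return df


# -- masks ----------------------------------------------------------------


def gen_section_masks(target_compactness: float, geometry: dict,
                      seed: int | np.random.Generator | None = None):
    """One synthetic bone cross-section mask with controlled compactness.

    The silhouette is a solid bar (or annulus segment) of the requested
    shell thickness; interior pixels at least one pixel away from the
    silhouette boundary are excavated one by one in random order until the
    realised porosity reaches 1 - target (cavities never touch the outer
    boundary, so hole-filling recovers the silhouette exactly).

    Returns (mask, realized_compactness).
    """
    if not 0 < target_compactness <= 1:
        raise ValueError("target compactness must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = geometry.get("shape", (48, 64))
    thick = int(geometry.get("thickness_px", 10))
    kind = geometry.get("kind", "bar")
    mask = np.zeros((h, w), dtype=bool)
    if kind == "bar":
        top = (h - thick) // 2
        mask[top : top + thick, 2 : w - 2] = True
    elif kind == "annulus":
        yy, xx = np.mgrid[:h, :w]
        cy, cx = h * 1.4, w / 2  # arc segment of a large annulus
        r_out = h * 1.3
        r = np.hypot(yy - cy, xx - cx)
        mask = (r <= r_out) & (r > r_out - thick)
        mask[:, :2] = False
        mask[:, -2:] = False
    else:
        raise ValueError(f"unknown silhouette kind {kind!r}")
    filled_n = int(mask.sum())
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask, iterations=1, border_value=0)
    interior = np.flatnonzero(eroded.ravel())
    target_cavity = int(round((1.0 - target_compactness) * filled_n))
    if target_cavity > len(interior):
        raise ValueError(
            f"target compactness {target_compactness} unreachable: "
            f"{target_cavity} cavity px needed, {len(interior)} interior px")
    dig = rng.permutation(interior)[:target_cavity]
    flat = mask.ravel().copy()
    flat[dig] = False
    out = flat.reshape(mask.shape)
    realized = float(out.sum()) / filled_n
    return out, realized


# -- full study -----------------------------------------------------------

_BONE_FRACTIONS = {"premaxilla": 0.08, "nasal": 0.22}  # frontal+parietal share 0.70


def _specimen_geometry(traits: pd.Series) -> dict:
    """Bone spans and section positions (mm) realising the planted ovl/rfp."""
    dia, elo, rfp, ovl = traits["dia"], traits["elo"], traits["rfp"], traits["ovl"]
    l_cran = elo * dia
    L = {
        "premaxilla": _BONE_FRACTIONS["premaxilla"] * l_cran,
        "nasal": _BONE_FRACTIONS["nasal"] * l_cran,
        "frontal": 0.70 * l_cran * rfp / (1 + rfp),
        "parietal": 0.70 * l_cran / (1 + rfp),
    }
    start = {"premaxilla": 0.0}
    order = list(BONES)
    for a, b in zip(order, order[1:]):
        # invert the overlap equation: ovl = 100*(2/3 - 2 delta/(LA+LB))
        delta = (2.0 / 3.0 - ovl / 100.0) * (L[a] + L[b]) / 2.0
        sec_a2 = start[a] + 2.0 * L[a] / 3.0
        start[b] = sec_a2 + delta - L[b] / 3.0
    total = start["parietal"] + L["parietal"]
    # rescale so the realised profile span equals l_cran: overlap and rfp
    # are scale-invariant, and downstream mm positions are s * l_cran
    scale = l_cran / total
    L = {b: v * scale for b, v in L.items()}
    start = {b: v * scale for b, v in start.items()}
    total = l_cran
    sections = {}
    for bone in order:
        sections[(bone, 1)] = (start[bone] + L[bone] / 3.0) / total
        sections[(bone, 2)] = (start[bone] + 2.0 * L[bone] / 3.0) / total
    return {"L": L, "start": start, "total_mm": total, "l_cran": l_cran,
            "sections": sections}


def gen_dataset(config: SimConfig | None = None, outdir=None,
                write_masks: bool = True):
    """Generate a complete synthetic study; optionally write it to disk.

    Returns a dict with the tree, lifestyle history, trait table, specimen
    table, masks and ground truth.  With ``outdir`` the study is also
    written in the formats the pipeline consumes (Newick, CSVs, PNG masks,
    ground_truth.json).
    """
    cfg = config if config is not None else SimConfig()
    rng = np.random.default_rng(cfg.seed)
    tree = gen_tree(cfg.n_tips, cfg.birth_rate, rng)
    # redraw the lifestyle history until the study is structurally valid:
    # enough independent fully-fossorial origins for convergence testing
    for _ in range(500):
        history = gen_lifestyle(tree, cfg.Q, rng, root_state=cfg.root_state)
        clades = fully_fossorial_clades(tree, history, cfg.min_clade_tips)
        counts = history.tip_states.value_counts()
        classes_ok = all(counts.get(s, 0) >= cfg.min_class_tips
                         for s in LIFESTYLES)
        if len(clades) >= cfg.min_fully_clades and classes_ok:
            break
    else:
        raise RuntimeError("could not realise enough fully fossorial clades")
    traits = gen_traits(tree, history, cfg.trait_specs, rng)

    specimen_rows = []
    masks: dict[tuple[str, str, int], np.ndarray] = {}
    truth_sections: dict[str, dict] = {}
    for taxon, row in traits.iterrows():
        geom = _specimen_geometry(row)
        wh_ratio = math.exp(rng.normal(0.0, 0.1))
        w_cran = row["dia"] * wh_ratio
        h_cran = row["dia"] / wh_ratio
        d_abs_target = row["d_rel_base"] / 100.0 * row["dia"]
        sec_truth = {}
        for bone in BONES:
            for idx in (1, 2):
                target_c = (row["c"] + rng.normal(0.0, cfg.section_noise_sd)) / 100.0
                target_c = min(max(target_c, 0.40), 0.995)
                # shell of >= 6 px so the lowest compactness targets stay
                # excavatable without cavities touching the boundary
                thick_px = max(int(round(d_abs_target / cfg.pixel_size_mm)), 6)
                mask, realized = gen_section_masks(
                    target_c,
                    {"shape": cfg.mask_shape, "thickness_px": thick_px,
                     "kind": "bar"},
                    rng,
                )
                masks[(taxon, bone, idx)] = mask
                sec_truth[f"{bone}{idx}"] = {
                    "target_compactness": target_c,
                    "realized_compactness": realized,
                    "thickness_px": thick_px,
                    "thickness_mm": thick_px * cfg.pixel_size_mm,
                }
                specimen_rows.append({
                    "taxon": taxon, "bone": bone, "section_index": idx,
                    "s_position": geom["sections"][(bone, idx)],
                    "bone_length_mm": geom["L"][bone],
                    "l_cran": geom["l_cran"], "w_cran": w_cran,
                    "h_cran": h_cran, "pixel_size_mm": cfg.pixel_size_mm,
                    "lifestyle": row["lifestyle"],
                    "mask_file": f"{taxon}_{bone}{idx}.png",
                })
        truth_sections[taxon] = sec_truth
    specimens = pd.DataFrame(specimen_rows)
    lifestyle = traits["lifestyle"].copy()
    truth = {
        "seed": cfg.seed,
        "n_tips": cfg.n_tips,
        "planted_trait": "c",
        "control_trait": "control",
        "n_transitions": history.n_transitions,
        "fully_clades": [sorted(c) for c in clades],
        "tip_traits": {t: {k: float(v) for k, v in r.items() if k != "lifestyle"}
                       for t, r in traits.iterrows()},
        "node_states": {str(u): s for u, s in history.node_states.items()},
        "sections": truth_sections,
    }
    study = {
        "tree": tree, "history": history, "traits": traits,
        "specimens": specimens, "lifestyle": lifestyle,
        "masks": masks, "focal_clades": clades, "ground_truth": truth,
        "config": cfg,
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(write_newick(tree) + "\n")
        specimens.to_csv(out / "specimens.csv", index=False)
        lifestyle.rename("lifestyle").to_csv(out / "lifestyle.csv")
        traits.to_csv(out / "traits_true.csv")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        pd.DataFrame(
            [{"clade_id": f"clade{i + 1}", "taxon": t}
             for i, c in enumerate(clades) for t in sorted(c)]
        ).to_csv(out / "focal_clades.csv", index=False)
        if write_masks:
            from PIL import Image

            mdir = out / "masks"
            mdir.mkdir(exist_ok=True)
            for (taxon, bone, idx), m in masks.items():
                img = Image.fromarray((m.astype(np.uint8)) * 255)
                img.save(mdir / f"{taxon}_{bone}{idx}.png")
    return study
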