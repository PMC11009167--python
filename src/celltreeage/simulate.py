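"""Synthetic cohorts: cell lineage trees, somatic SNV carriage, UMI noise.

The generator emulates the statistical structure the downstream pipeline
assumes: each sample is a population of blood cells grown from a single
founder by a discrete-generation birth process, accumulating somatic SNVs
under an infinite-sites model (each division deposits a Poisson number of
new variants into one daughter lineage). Lineage depth scales with donor
age — ``divisions_base`` founder divisions plus ``divisions_per_year`` per
year of life — so older samples carry more mutations and, through random
drift and optional clonal expansions, more imbalanced trees. Observation
noise mimics UMI-based single-cell SNV calling: per cell and site the total
UMI depth is Poisson, zeroed entirely with a dropout probability; carrier
cells yield alternative-allele UMIs, non-carriers reference UMIs.

The process is desk-scale: the population is capped by uniform lineage
subsampling and the final tree is a uniform sample of ``cells_per_sample``
tips, not an explicit organism-sized population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .trees import CellTree
from .variants import VariantCallMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are tuned to the cohorts the pipeline targets: ~1400 cells per
    sample, adult donors, and a mutation/observation regime in which a few
    thousand variant sites per sample survive the detection filters.
    """

    n_samples: int = 18
    age_range: tuple = (21.0, 82.0)
    cells_per_sample: int = 1400
    #: founder-to-sample divisions at age 0
    divisions_base: float = 30.0
    #: additional expected divisions per year of age
    divisions_per_year: float = 1.0
    #: mean new SNVs per division (Poisson), deposited into one daughter
    mu_div: float = 0.3
    #: probability per year of age that one driver clone expands
    clone_rate_per_year: float = 0.01
    #: multiplicative division-rate factor of the driver clone
    clone_advantage: float = 2.0
    #: mean UMIs covering a site in a cell (Poisson)
    depth_mean: float = 12.0
    #: probability that a covered site yields zero UMIs
    dropout: float = 0.6
    #: per-sample sex labels ('F'/'M'); default alternates
    sex_assignment: list | None = None
    seed: int = 0
    #: explicit per-sample ages; default uniform over age_range
    ages: list | None = None
    #: per-generation division probability of the base process
    division_prob: float = 0.5
    #: population cap = pop_cap_factor * cells_per_sample; the cap stands in
    #: for the stem-cell pool, which is much larger than the sampled cell
    #: count — genealogy sampling noise shrinks as the pool grows
    pop_cap_factor: int = 16

    def validate(self) -> None:
        low, high = self.age_range
        if low > high:
            raise ValueError(f"age_range low {low} > high {high}")
        if self.cells_per_sample < 3:
            raise ValueError("cells_per_sample must be >= 3")
        for name in ("n_samples", "divisions_base", "divisions_per_year", "mu_div",
                     "clone_rate_per_year", "depth_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if not 0.0 < self.division_prob <= 1.0:
            raise ValueError("division_prob must be in (0, 1]")
        if self.clone_advantage < 1.0:
            raise ValueError("clone_advantage must be >= 1")
        if self.ages is not None and len(self.ages) != self.n_samples:
            raise ValueError("ages list length must equal n_samples")


@dataclass
class TruthRecord:
    """Ground truth for one simulated sample."""

    sample_id: str
    true_tree: CellTree
    #: barcode -> frozenset of variant ids carried by that cell
    per_cell_mutations: dict
    age: float
    sex: str
    #: realized division counts (diagnostics for the Monte-Carlo oracles)
    n_divisions_total: int = 0
    n_divisions_retained: int = 0
    n_divisions_both_retained: int = 0

    @property
    def variant_ids(self) -> list:
        ids = set()
        for s in self.per_cell_mutations.values():
            ids.update(s)
        return sorted(ids)

    def carrier_sets(self) -> dict:
        """variant id -> frozenset of carrier barcodes."""
        out: dict = {}
        for cell, muts in self.per_cell_mutations.items():
            for v in muts:
                out.setdefault(v, set()).add(cell)
        return {v: frozenset(c) for v, c in out.items()}


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def simulate_lineage(age: float, cfg: SimConfig, rng_state=None, sample_id: str = "S0",
                     sex: str = "F") -> TruthRecord:
    """Grow one sample's cell lineage tree and its somatic variants.

    A single founder divides over ``round((divisions_base +
    divisions_per_year * age) / division_prob)`` discrete generations, each
    lineage dividing with probability ``division_prob`` per generation (so
    the expected number of divisions per surviving lineage is the configured
    total). With probability ``clone_rate_per_year * age`` (capped at 1) one
    uniformly chosen lineage at a uniformly chosen generation becomes a
    driver clone whose division probability is multiplied by
    ``clone_advantage`` from its origin onward. The population is capped at
    ``pop_cap_factor * cells_per_sample`` by uniform subsampling, and
    ``cells_per_sample`` tips are sampled uniformly at the end.

    Each division deposits Poisson(``mu_div``) new variants into one
    uniformly chosen daughter (infinite sites: variants are never lost and
    never recur), so a variant's carriers are exactly the tips of one clade.
    Branch lengths of the returned tree count the variants on each edge.
    """
    cfg.validate()
    low, high = cfg.age_range
    if not (low <= age <= high):
        raise ValueError(f"age {age} outside configured age_range {cfg.age_range}")
    rng = _as_rng(rng_state)

    p = cfg.division_prob
    p_clone = min(1.0, p * cfg.clone_advantage)
    n_gen = max(int(round((cfg.divisions_base + cfg.divisions_per_year * age) / p)), 0)
    cap = max(cfg.pop_cap_factor * cfg.cells_per_sample, cfg.cells_per_sample)

    clone_happens = bool(rng.random() < min(1.0, cfg.clone_rate_per_year * age))
    clone_gen = int(rng.integers(0, n_gen)) if n_gen > 0 else 0

    parent_list = [-1]
    n_nodes = 1
    alive = np.array([0], dtype=np.int64)
    clone = np.zeros(1, dtype=bool)
    n_divisions = 0

    for g in range(n_gen):
        if clone_happens and g == clone_gen:
            clone[int(rng.integers(len(alive)))] = True
        pdiv = np.where(clone, p_clone, p)
        div = rng.random(len(alive)) < pdiv
        k = int(div.sum())
        if k:
            new = np.arange(n_nodes, n_nodes + 2 * k, dtype=np.int64)
            parent_list.extend(np.repeat(alive[div], 2).tolist())
            n_nodes += 2 * k
            n_divisions += k
            alive = np.concatenate([alive[~div], new])
            clone = np.concatenate([clone[~div], np.repeat(clone[div], 2)])
        if len(alive) > cap:
            keep = np.sort(rng.choice(len(alive), size=cap, replace=False))
            alive = alive[keep]
            clone = clone[keep]

    if len(alive) < cfg.cells_per_sample:
        raise RuntimeError(
            f"sample {sample_id}: population {len(alive)} below cells_per_sample "
            f"{cfg.cells_per_sample}; increase divisions_base or division_prob"
        )
    tips = np.sort(rng.choice(alive, size=cfg.cells_per_sample, replace=False))
    parent = np.asarray(parent_list, dtype=np.int64)

    # --- prune to ancestors of the sampled tips -------------------------
    keep = np.zeros(n_nodes, dtype=bool)
    for t in tips:
        v = int(t)
        while v != -1 and not keep[v]:
            keep[v] = True
            v = int(parent[v])
    ret_nodes = np.flatnonzero(keep)
    ret_child_count = np.zeros(n_nodes, dtype=np.int32)
    nonroot = ret_nodes[ret_nodes != 0]
    np.add.at(ret_child_count, parent[nonroot], 1)

    tip_set = set(int(t) for t in tips)
    divisions_ret = np.array([v for v in ret_nodes if v not in tip_set], dtype=np.int64)
    n_both = int((ret_child_count[divisions_ret] == 2).sum()) if divisions_ret.size else 0

    # --- visible mutation bundles on retained divisions -----------------
    ret_children: dict = {}
    for v in nonroot:
        ret_children.setdefault(int(parent[v]), []).append(int(v))
    bundle_counts = rng.poisson(cfg.mu_div, size=len(divisions_ret))
    bundle_side = rng.random(len(divisions_ret))
    bundles: dict = {}  # chosen retained daughter -> number of variants
    for d, kvar, u in zip(divisions_ret, bundle_counts, bundle_side):
        if kvar == 0:
            continue
        kids = sorted(ret_children.get(int(d), []))
        if len(kids) == 2:
            target = kids[0] if u < 0.5 else kids[1]
        elif len(kids) == 1:
            # the unseen daughter got the bundle with probability 1/2
            target = kids[0] if u < 0.5 else None
        else:
            target = None
        if target is not None:
            bundles[target] = bundles.get(target, 0) + int(kvar)

    # --- collapse unary chains into a sampled tree ----------------------
    kept = {0} | tip_set | {int(v) for v in divisions_ret if ret_child_count[v] == 2}
    kept_parent: dict = {}
    edge_vars: dict = {}  # kept node -> number of variants on edge above it
    for v in sorted(kept):
        if v == 0:
            continue
        nvar = bundles.get(v, 0)
        u = int(parent[v])
        while u not in kept:
            nvar += bundles.get(u, 0)
            u = int(parent[u])
        kept_parent[v] = u
        edge_vars[v] = nvar

    children: dict = {v: [] for v in kept}
    for v, u in kept_parent.items():
        children[u].append(v)
    children = {v: tuple(sorted(c)) for v, c in children.items() if c}

    # assign variant ids per edge, then accumulate carriage down the tree
    var_counter = 0
    edge_variant_ids: dict = {}
    for v in sorted(edge_vars):
        ids = [f"{sample_id}:v{var_counter + i}" for i in range(edge_vars[v])]
        var_counter += edge_vars[v]
        edge_variant_ids[v] = ids

    tip_order = {int(t): i for i, t in enumerate(tips)}
    barcodes = {int(t): f"{sample_id}-c{i:05d}" for i, t in enumerate(tips)}
    per_cell: dict = {}
    stack = [(0, [])]
    while stack:
        v, acc = stack.pop()
        acc = acc + edge_variant_ids.get(v, [])
        if v in tip_order:
            per_cell[barcodes[v]] = frozenset(acc)
        for ch in children.get(v, ()):
            stack.append((ch, acc))

    edge_length = {v: float(n) for v, n in edge_vars.items()}
    tree = CellTree.from_children(children, edge_length, barcodes, root=0, ultrametric=False)
    return TruthRecord(
        sample_id=sample_id,
        true_tree=tree,
        per_cell_mutations=per_cell,
        age=float(age),
        sex=sex,
        n_divisions_total=n_divisions,
        n_divisions_retained=len(divisions_ret),
        n_divisions_both_retained=n_both,
    )


def observe_umis(truth: TruthRecord, cfg: SimConfig, rng_state=None) -> VariantCallMatrix:
    """Turn true SNV carriage into noisy sparse alt/ref UMI count matrices.

    Per cell and variant site the total UMI depth is Poisson(``depth_mean``),
    zeroed with probability ``dropout``. All UMIs of a carrier cell support
    the alternative allele; all UMIs of a non-carrier support the reference.
    Variant annotations (chrom, pos, ref, alt; 1-based) are synthesized.
    """
    cfg.validate()
    rng = _as_rng(rng_state)
    barcodes = truth.true_tree.tip_labels  # stable order: the truth tree's tip order
    variant_ids = truth.variant_ids
    n_cells, n_sites = len(barcodes), len(variant_ids)

    vidx = {v: j for j, v in enumerate(variant_ids)}
    rows, cols = [], []
    for i, b in enumerate(barcodes):
        for v in truth.per_cell_mutations[b]:
            rows.append(i)
            cols.append(vidx[v])
    carrier = sp.csr_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n_cells, n_sites)
    ).toarray() if n_sites else np.zeros((n_cells, 0), dtype=bool)

    alt_blocks, ref_blocks = [], []
    chunk = 2048
    for j0 in range(0, n_sites, chunk):
        j1 = min(j0 + chunk, n_sites)
        depth = rng.poisson(cfg.depth_mean, size=(n_cells, j1 - j0))
        if cfg.dropout > 0:
            depth[rng.random((n_cells, j1 - j0)) < cfg.dropout] = 0
        carr = carrier[:, j0:j1]
        alt_blocks.append(sp.csr_matrix(np.where(carr, depth, 0)))
        ref_blocks.append(sp.csr_matrix(np.where(carr, 0, depth)))
    if alt_blocks:
        alt = sp.hstack(alt_blocks, format="csr")
        ref = sp.hstack(ref_blocks, format="csr")
    else:
        alt = sp.csr_matrix((n_cells, 0), dtype=np.int64)
        ref = sp.csr_matrix((n_cells, 0), dtype=np.int64)

    refs = _BASES[rng.integers(0, 4, size=n_sites)] if n_sites else np.array([], dtype="U1")
    alts = np.array(
        [_BASES[(list(_BASES).index(r) + int(o)) % 4] for r, o in
         zip(refs, rng.integers(1, 4, size=n_sites))],
        dtype="U1",
    ) if n_sites else np.array([], dtype="U1")
    sites = pd.DataFrame({
        "chrom": [f"chr{(j % 22) + 1}" for j in range(n_sites)],
        "pos": [1000 + j for j in range(n_sites)],
        "ref": refs,
        "alt": alts,
        "variant_id": variant_ids,
    })
    return VariantCallMatrix(alt_umis=alt, ref_umis=ref, barcodes=barcodes, sites=sites)


def simulate_cohort(cfg: SimConfig, out_dir=None):
    """Simulate a full cohort; optionally write it to disk.

    Returns ``(matrices, truths, metadata)`` where ``metadata`` is a
    DataFrame with columns ``sample_id, age, sex``. Ages are uniform over
    ``cfg.age_range`` unless ``cfg.ages`` is given. Per-sample random
    streams are derived independently from ``cfg.seed``, so the outputs for
    sample *k* do not depend on any other sample.
    """
    cfg.validate()
    n = cfg.n_samples
    sample_ids = [f"S{k + 1:02d}" for k in range(n)]
    if cfg.ages is not None:
        ages = [float(a) for a in cfg.ages]
    else:
        age_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
        low, high = cfg.age_range
        ages = list(age_rng.uniform(low, high, size=n))
    if cfg.sex_assignment is not None:
        if len(cfg.sex_assignment) != n:
            raise ValueError("sex_assignment length must equal n_samples")
        sexes = [str(s) for s in cfg.sex_assignment]
    else:
        sexes = ["F" if k % 2 == 0 else "M" for k in range(n)]

    matrices, truths = [], []
    for k in range(n):
        rng_sim = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1, k)))
        rng_obs = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2, k)))
        truth = simulate_lineage(ages[k], cfg, rng_sim, sample_id=sample_ids[k], sex=sexes[k])
        vcm = observe_umis(truth, cfg, rng_obs)
        truths.append(truth)
        matrices.append(vcm)

    metadata = pd.DataFrame({"sample_id": sample_ids, "age": ages, "sex": sexes})

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            metadata.to_csv(out / "metadata.csv", index=False)
            for truth, vcm in zip(truths, matrices):
                sdir = out / truth.sample_id
                vcm.write(sdir)
                with open(sdir / "truth.nwk", "w") as fh:
                    fh.write(truth.true_tree.as_newick() + "\n")
                carriage = pd.DataFrame(
                    [(cell, v) for cell, muts in truth.per_cell_mutations.items()
                     for v in sorted(muts)],
                    columns=["barcode", "variant_id"],
                )
                carriage.to_csv(sdir / "truth_carriage.csv", index=False)
        except OSError as exc:
            raise OSError(f"failed writing cohort output under {out}: {exc}") from exc

    return matrices, truths, metadata


def scaled_config(cfg: SimConfig, cells_per_sample: int) -> SimConfig:
    """Convenience: same cohort conditions at a smaller number of cells."""
    return replace(cfg, cells_per_sample=cells_per_sample)
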