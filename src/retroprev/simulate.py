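"""Synthetic phylogenies, traits, necropsy tallies, and annotation landscapes.

Every generator is seed-deterministic and returns its ground truth alongside
the data, so each pipeline stage can be tested end to end without the real
genome assemblies or the zoological necropsy database:

* pure-birth ultrametric phylogenies (tree shape itself is not a quantity of
  interest here, so the simplest ultrametric model is used);
* species traits drawn from a lambda-structured phylogenetic covariance plus
  a diagonal sampling-error term — exactly the generative model assumed by
  :func:`retroprev.pgls.fit_pgls`;
* necropsy tallies sampled hierarchically, neoplasia ~ Binomial(n, prevalence)
  and malignant ~ Binomial(neoplasia, conversion fraction), which guarantees
  the count-nesting invariant of the cohort records;
* genome-scale repeat/gene interval landscapes with known active counts,
  genic-insertion counts, and nearest-gene distances (the truth distances are
  computed by an O(n*m) brute-force scan, independent of the pipeline's
  sorted-search implementation).

:func:`simulate_study` combines these into a paper-like cohort dataset on disk
(Newick tree, cohort TSV, per-species repeat/gene BED files, orthogroup
tables, YAML config) in the exact formats the real pipeline reads.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import dendropy
import yaml

from .proximity import GeneRecord
from .repeats import RepeatRecord, write_repeat_bed
from . import pgls

__all__ = [
    "SyntheticTruth",
    "simulate_tree",
    "simulate_traits",
    "simulate_necropsies",
    "simulate_repeat_landscape",
    "simulate_study",
]

L1_ACTIVE_LEN = (5490, 6710)  # +/-10% of the 6.1 kb consensus
SINE_ACTIVE_LEN = (100, 400)
ACTIVE_MAX_DIV = 5.0


@dataclass
class SyntheticTruth:
    """Ground truth carried by every generated dataset."""

    seed: int
    tree: Optional[dendropy.Tree] = None
    lambda_true: Optional[float] = None
    sigma2_true: Optional[float] = None
    beta_true: Optional[np.ndarray] = None
    true_prevalence: Optional[np.ndarray] = None
    n_active_l1: Optional[int] = None
    n_active_sine: Optional[int] = None
    genic_insertions: Optional[int] = None
    distances: Optional[np.ndarray] = None
    extras: dict = field(default_factory=dict)


def simulate_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with tips sp001..spNNN.

    Branching times follow the standard Yule construction: with k extant
    lineages the next split arrives after Exponential(k) time; a uniformly
    chosen lineage splits. All tip depths are equal by construction and the
    total depth is rescaled to 1.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    birth: dict[int, float] = {}
    active: list = []
    for _ in range(2):
        ch = root.new_child(edge_length=0.0)
        birth[id(ch)] = 0.0
        active.append(ch)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.expovariate(len(active))
        node = active.pop(rng.randrange(len(active)))
        node.edge.length = t - birth[id(node)]
        for _ in range(2):
            ch = node.new_child(edge_length=0.0)
            birth[id(ch)] = t
            active.append(ch)
    t += rng.expovariate(len(active))  # run to the common sampling time
    for node in active:
        node.edge.length = t - birth[id(node)]
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"sp{i + 1:03d}")
    _rescale_depth(tree, 1.0)
    return tree


def _rescale_depth(tree: dendropy.Tree, target: float) -> None:
    depths = {}
    for node in tree.preorder_node_iter():
        el = node.edge.length or 0.0
        depths[id(node)] = (depths[id(node.parent_node)] if node.parent_node else 0.0) + el
    current = max(depths[id(l)] for l in tree.leaf_node_iter())
    f = target / current
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= f


def simulate_traits(
    C: np.ndarray,
    lambda_true: float,
    sigma2_true: float,
    beta_true: Sequence[float],
    X: np.ndarray,
    w: Optional[Sequence[float]],
    seed: int,
) -> np.ndarray:
    """Draw y ~ Normal(X beta, sigma^2 C(lambda) + diag(w^2))."""
    rng = np.random.default_rng(seed)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta_true = np.asarray(beta_true, dtype=float)
    n = X.shape[0]
    V = sigma2_true * pgls.lambda_transform(C, lambda_true)
    if w is not None:
        V = V + np.diag(np.asarray(w, dtype=float) ** 2)
    mean = X @ beta_true
    if not np.any(V):
        return mean.copy()
    eigmin = float(np.linalg.eigvalsh(V).min())
    if eigmin < -1e-8 * np.trace(V) / n:
        raise ValueError("covariance is not positive semi-definite")
    L = np.linalg.cholesky(V + max(0.0, -eigmin + 1e-12) * np.eye(n)) if eigmin <= 0 else np.linalg.cholesky(V)
    return mean + L @ rng.standard_normal(n)


def simulate_necropsies(
    true_prevalence: Sequence[float],
    n_per_species: Sequence[int],
    seed: int,
    malignant_fraction: float | Sequence[float] = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial necropsy tallies: (neoplasia counts, malignant counts).

    Malignant counts are drawn as binomial subsets of the neoplasia counts so
    the nesting 0 <= malignant <= neoplasia <= n always holds.
    """
    p = np.asarray(true_prevalence, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("prevalences must lie in [0, 1]")
    n = np.asarray(n_per_species, dtype=int)
    rng = np.random.default_rng(seed)
    neo = rng.binomial(n, p)
    mf = np.broadcast_to(np.asarray(malignant_fraction, dtype=float), neo.shape)
    mal = rng.binomial(neo, mf)
    return neo, mal


def _brute_force_closest(q, targets) -> Optional[int]:
    best = None
    for t in targets:
        if t.chrom != q.chrom:
            continue
        if t.start < q.end and t.end > q.start:
            return 0
        gap = max(t.start - q.end, q.start - t.end)
        best = gap if best is None else min(best, gap)
    return best


def simulate_repeat_landscape(
    genome_length: int = 2_000_000,
    n_genes: int = 50,
    n_l1: int = 60,
    n_sine: int = 120,
    active_frac_l1: float = 0.3,
    active_frac_sine: float = 0.3,
    seed: int = 0,
    n_chroms: int = 2,
) -> tuple[list[RepeatRecord], list[GeneRecord], SyntheticTruth]:
    """Random annotation landscape with exact known activity ground truth.

    Active elements get lengths inside the activity windows (L1 [5490, 6710],
    SINE [100, 400]) and divergence <= 5%; inactive elements violate at least
    one criterion (length outside the window, divergence above 5%, or both).
    Truth records the active counts, the genic-insertion count of the active
    set, and the nearest-gene distance of every active element computed by a
    brute-force all-pairs scan.
    """
    rng = np.random.default_rng(seed)
    chrom_len = genome_length // n_chroms
    if chrom_len < 100_000:
        raise ValueError("genome too short for the requested layout")
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]

    def place(length: int) -> tuple[str, int, int]:
        c = chroms[int(rng.integers(n_chroms))]
        if length >= chrom_len:
            raise ValueError("infeasible packing: element longer than chromosome")
        s = int(rng.integers(0, chrom_len - length))
        return c, s, s + length

    genes: list[GeneRecord] = []
    for i in range(n_genes):
        glen = int(rng.integers(2_000, 50_000))
        c, s, e = place(glen)
        genes.append(GeneRecord(chrom=c, start=s, end=e, gene_id=f"gene{i + 1:04d}"))

    repeats: list[RepeatRecord] = []
    n_active_l1 = int(round(n_l1 * active_frac_l1))
    n_active_sine = int(round(n_sine * active_frac_sine))

    def rand_strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    def inactive_length(active_lo: int, active_hi: int, max_len: int) -> int:
        if rng.random() < 0.5 and active_lo > 50:
            return int(rng.integers(30, active_lo))  # truncated copy
        return int(rng.integers(active_hi + 1, max_len))

    for i in range(n_l1):
        if i < n_active_l1:
            length = int(rng.integers(L1_ACTIVE_LEN[0], L1_ACTIVE_LEN[1] + 1))
            div = float(rng.uniform(0.0, ACTIVE_MAX_DIV))
        else:
            mode = rng.random()
            if mode < 0.5:  # bad length, any divergence
                length = inactive_length(*L1_ACTIVE_LEN, max_len=9_000)
                div = float(rng.uniform(0.0, 30.0))
            else:  # good length, bad divergence
                length = int(rng.integers(L1_ACTIVE_LEN[0], L1_ACTIVE_LEN[1] + 1))
                div = float(rng.uniform(ACTIVE_MAX_DIV + 0.5, 30.0))
        c, s, e = place(length)
        repeats.append(RepeatRecord(c, s, e, rand_strand(), "L1", round(div, 2)))
    for i in range(n_sine):
        if i < n_active_sine:
            length = int(rng.integers(SINE_ACTIVE_LEN[0], SINE_ACTIVE_LEN[1] + 1))
            div = float(rng.uniform(0.0, ACTIVE_MAX_DIV))
        else:
            mode = rng.random()
            if mode < 0.5:
                length = inactive_length(*SINE_ACTIVE_LEN, max_len=1_500)
                div = float(rng.uniform(0.0, 30.0))
            else:
                length = int(rng.integers(SINE_ACTIVE_LEN[0], SINE_ACTIVE_LEN[1] + 1))
                div = float(rng.uniform(ACTIVE_MAX_DIV + 0.5, 30.0))
        c, s, e = place(length)
        repeats.append(RepeatRecord(c, s, e, rand_strand(), "SINE", round(div, 2)))

    # shuffle so active/inactive order carries no signal
    order = rng.permutation(len(repeats))
    repeats = [repeats[i] for i in order]

    active = [
        r
        for r in repeats
        if (
            r.superfamily == "L1"
            and L1_ACTIVE_LEN[0] <= r.length <= L1_ACTIVE_LEN[1]
            and r.divergence <= ACTIVE_MAX_DIV
        )
        or (
            r.superfamily == "SINE"
            and SINE_ACTIVE_LEN[0] <= r.length <= SINE_ACTIVE_LEN[1]
            and r.divergence <= ACTIVE_MAX_DIV
        )
    ]
    genic = sum(
        1 for r in active if any(
            g.chrom == r.chrom and g.start < r.end and g.end > r.start for g in genes
        )
    )
    distances = [
        d for d in (_brute_force_closest(r, genes) for r in active) if d is not None
    ]
    truth = SyntheticTruth(
        seed=seed,
        n_active_l1=n_active_l1,
        n_active_sine=n_active_sine,
        genic_insertions=genic,
        distances=np.asarray(distances, dtype=np.int64),
    )
    return repeats, genes, truth


def simulate_study(
    out_dir: str | Path,
    seed: int,
    n_species: int = 55,
    lambda_true: float = 0.5,
    prevalence_noise_sd: float = 0.03,
    effect_span: float = 0.5,
    baseline_prevalence: float = 0.03,
    malignant_fraction: float = 0.4,
    n_cancer_genes: int = 30,
    landscape_kwargs: Optional[dict] = None,
) -> SyntheticTruth:
    """Write a complete paper-like synthetic dataset and return its truth.

    Per-species combined L1+SINE activity is drawn with phylogenetic signal
    (log-normal on a lambda-structured latent), and true neoplasia prevalence
    increases linearly with the min-max-scaled log activity over ``effect_span``
    of the prevalence range, plus Brownian noise. Necropsy totals are
    log-uniform on [20, 500]. Outputs: tree.nwk, cohort.tsv, repeats/<sp>.bed,
    genes/<sp>.bed, cgo_flags.tsv, cancer_genes.tsv, Orthogroups[.GeneCount].tsv,
    and config.yaml wired to these paths.
    """
    out = Path(out_dir)
    (out / "repeats").mkdir(parents=True, exist_ok=True)
    (out / "genes").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)

    tree = simulate_tree(n_species, seed=seed)
    tree.write(path=str(out / "tree.nwk"), schema="newick")
    cov = pgls.vcv_from_tree(tree)
    species = cov.labels
    C = cov.C

    # latent activity with phylogenetic signal
    u = simulate_traits(C, lambda_true, 1.0, [0.0], np.ones((n_species, 1)),
                        None, seed=seed + 1)
    target_combined = np.round(np.exp(3.5 + 1.2 * u)).astype(int) + 2

    lk = dict(genome_length=1_000_000, n_genes=40, seed=0, n_chroms=2)
    lk.update(landscape_kwargs or {})
    active_frac = 0.3
    truth_counts = {}
    all_truths = {}
    for i, sp in enumerate(species):
        combined = int(target_combined[i])
        n_active_l1_t = combined // 3
        n_active_sine_t = combined - n_active_l1_t
        kw = dict(lk)
        kw["seed"] = int((seed * 100_003 + i * 97) % (2**31 - 1))
        kw["n_l1"] = max(1, int(round(n_active_l1_t / active_frac)))
        kw["n_sine"] = max(1, int(round(n_active_sine_t / active_frac)))
        kw["active_frac_l1"] = n_active_l1_t / kw["n_l1"]
        kw["active_frac_sine"] = n_active_sine_t / kw["n_sine"]
        repeats, genes, t = simulate_repeat_landscape(**kw)
        truth_counts[sp] = (t.n_active_l1, t.n_active_sine)
        all_truths[sp] = t
        write_repeat_bed(repeats, out / "repeats" / f"{sp}.bed")
        with open(out / "genes" / f"{sp}.bed", "w") as fh:
            for g in genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t+\n")

    combined_true = np.array([sum(truth_counts[sp]) for sp in species], dtype=float)
    z = np.log1p(combined_true)
    z = (z - z.min()) / max(np.ptp(z), 1e-12)
    bm_noise = simulate_traits(C, 1.0, prevalence_noise_sd**2, [0.0],
                               np.ones((n_species, 1)), None, seed=seed + 2)
    prev = np.clip(baseline_prevalence + effect_span * z + bm_noise, 0.005, 0.95)

    n_necropsies = np.round(np.exp(rng.uniform(np.log(20), np.log(500), n_species))).astype(int)
    neo, mal = simulate_necropsies(prev, n_necropsies, seed=seed + 3,
                                   malignant_fraction=malignant_fraction)
    mal = np.maximum(mal, (neo > 0).astype(int))  # keep malignancy observable
    longevity = np.round(np.exp(rng.normal(5.0, 0.6, n_species))).astype(int)

    with open(out / "cohort.tsv", "w") as fh:
        fh.write("species_id\tn_necropsies\tn_neoplasia\tn_malignant\tlongevity_months\n")
        for i, sp in enumerate(species):
            fh.write(f"{sp}\t{n_necropsies[i]}\t{neo[i]}\t{mal[i]}\t{longevity[i]}\n")

    _write_synthetic_orthogroups(out, species, n_cancer_genes, rng)

    config = {
        "seed": int(seed),
        "paths": {
            "tree": "tree.nwk",
            "cohort": "cohort.tsv",
            "repeats_dir": "repeats",
            "repeat_dialect": "bed",
            "genes_dir": "genes",
            "cgo_flags": "cgo_flags.tsv",
            "cancer_genes": "cancer_genes.tsv",
            "orthogroups": "Orthogroups.tsv",
            "orthogroup_counts": "Orthogroups.GeneCount.tsv",
            "query_species": "human",
        },
        "thresholds": {"min_necropsies": 20},
        "models": {
            "families": ["abundance", "proximity_mean", "genic_insertion", "cgo_load"],
            "responses": ["neoplasia", "malignancy"],
            "include_longevity": False,
        },
        "fdr_q": 0.05,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    truth = SyntheticTruth(
        seed=seed,
        tree=tree,
        lambda_true=lambda_true,
        sigma2_true=prevalence_noise_sd**2,
        beta_true=np.array([baseline_prevalence, effect_span]),
        true_prevalence=prev,
        extras={
            "species": species,
            "truth_counts": truth_counts,
            "landscape_truths": all_truths,
            "n_necropsies": n_necropsies,
            "neoplasia": neo,
            "malignant": mal,
        },
    )
    return truth


def _write_synthetic_orthogroups(out: Path, species, n_cancer_genes: int, rng) -> None:
    """Small synthetic Cancer-Gene-Census + OrthoFinder tables (text layout)."""
    roles = ["oncogene", "tsg", "both", "other"]
    with open(out / "cancer_genes.tsv", "w") as fh:
        fh.write("symbol\tprotein_id\tsomatic\tgermline\trole\tfusion\n")
        for i in range(n_cancer_genes):
            som = rng.random() < 0.8
            germ = (rng.random() < 0.3) or not som
            role = roles[int(rng.integers(len(roles)))]
            fus = rng.random() < 0.25
            fh.write(
                f"CG{i + 1:03d}\tP{i + 1:05d}\t{int(som)}\t{int(germ)}\t{role}\t{int(fus)}\n"
            )
    cols = ["human"] + list(species)
    with open(out / "Orthogroups.tsv", "w") as gfh, open(
        out / "Orthogroups.GeneCount.tsv", "w"
    ) as cfh:
        gfh.write("Orthogroup\t" + "\t".join(cols) + "\n")
        cfh.write("Orthogroup\t" + "\t".join(cols) + "\tTotal\n")
        for i in range(n_cancer_genes):
            og = f"OG{i:07d}"
            members = {"human": [f"P{i + 1:05d}"]}
            for sp in species:
                k = int(rng.poisson(1.2))
                members[sp] = [f"{sp}_g{i}_{j}" for j in range(k)]
            gfh.write(og + "\t" + "\t".join(", ".join(members[c]) for c in cols) + "\n")
            counts = [len(members[c]) for c in cols]
            cfh.write(og + "\t" + "\t".join(map(str, counts)) + f"\t{sum(counts)}\n")
    with open(out / "cgo_flags.tsv", "w") as fh:
        fh.write("gene_id\tcategories\n")
        # flag ~20% of gene ids per species as CGOs in the gene BEDs
        for sp in species:
            for i in range(40):
                if (i * 7 + 3) % 5 == 0:
                    fh.write(f"gene{i + 1:04d}\tsomatic,oncogene\n")
            break  # gene ids are shared across species files
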