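"""F2 population and quantitative-trait simulator.

An F2 individual from a cross of two inbred lines carries two gametes, each a
Markov walk along the genetic map: the first allele is Bernoulli(1/2) and
successive alleles flip with the Haldane recombination fraction
r(d) = (1 - exp(-2d/100)) / 2 for an inter-marker distance of d cM (no
crossover interference).  The coded genotype Z = (allele sum) - 1 then has
the F2 properties Var(Z) = 1/2 and Cov(Z_h, Z_l) = (1 - 2 r_hl) / 2.

Four preset trait architectures are provided:

I   oligogenic          — dense map (0.02 cM spacing on 2400 cM), 20 main QTL
                          plus 20 pairwise epistatic effects;
II  clustered polygenic — each main QTL split into a cluster of 500 equal
                          small QTL within +/-5 cM;
III uniform polygenic   — 1000 equal QTL evenly placed, first half positive,
                          second half negative;
IV  oligogenic, no LD   — 100 cM marker spacing (12,000,000 cM genome), so
                          adjacent markers are essentially independent.

Per-QTL effects for the oligogenic designs are not fully specified by their
aggregate variances; presets use a fixed, documented effect palette rescaled
analytically so the main-effect genetic variance matches the design target
(64.12 for I/IV; 81.94 for II/III).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GenotypeMatrix, MarkerMap, PhenotypeVector

__all__ = [
    "haldane",
    "f2_covariance",
    "simulate_f2",
    "simulate_phenotype",
    "heritability",
    "SimDesign",
    "SimulatedDataset",
    "design_preset",
    "simulate_dataset",
    "evenly_spaced_map",
]

#: aggregate variance targets printed for the four architectures
MAIN_VARIANCE_I = 64.12
EPISTATIC_VARIANCE_I = 26.52
GENETIC_VARIANCE_II_III = 81.94
#: Design IV phenotypic variance; residual variance chosen as their difference
PHENOTYPIC_VARIANCE_IV = 89.71


def haldane(d_cM):
    """Haldane map function: cM distance -> recombination fraction."""
    d = np.asarray(d_cM, dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def f2_covariance(d_cM):
    """Cov(Z_h, Z_l) between F2 genotype indicators at map distance d cM.

    Each gamete allele pair has Cov = (1-2r)/4; the two gametes are
    independent, giving (1 - 2 r) / 2 on the diploid coding.
    """
    return (1.0 - 2.0 * haldane(d_cM)) / 2.0


def evenly_spaced_map(
    genome_length: float, spacing: float, chromosome: str = "1"
) -> MarkerMap:
    """Markers every ``spacing`` cM from 0 to ``genome_length`` inclusive."""
    n = int(round(genome_length / spacing)) + 1
    pos = np.arange(n) * spacing
    ids = np.array([f"m{i + 1}" for i in range(n)], dtype=object)
    chrom = np.full(n, chromosome, dtype=object)
    return MarkerMap(ids, chrom, genetic_pos=pos)


def simulate_f2(n: int, mmap: MarkerMap, seed=None) -> GenotypeMatrix:
    """Simulate n F2 individuals on the genetic map.

    ``seed`` may be an int or a numpy Generator; identical seeds give
    bitwise-identical genotypes.
    """
    if mmap.genetic_pos is None:
        raise ValueError("F2 simulation requires genetic (cM) positions")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = mmap.n_markers
    gametes = np.empty((2 * n, p), dtype=np.int8)
    for sl in mmap.chromosome_slices().values():
        pos = mmap.genetic_pos[sl]
        r = haldane(np.diff(pos))
        block = np.empty((2 * n, len(pos)), dtype=np.int8)
        block[:, 0] = rng.random(2 * n) < 0.5
        if len(pos) > 1:
            block[:, 1:] = rng.random((2 * n, len(pos) - 1)) < r[None, :]
        np.bitwise_xor.accumulate(block, axis=1, out=block)
        gametes[:, sl] = block
    geno = gametes[:n].astype(float) + gametes[n:].astype(float) - 1.0
    ids = np.array([f"F2_{i + 1:05d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(geno, ids)


def heritability(var_main: float, var_epi: float, sigma2_e: float) -> float:
    """Proportion of phenotypic variance contributed by the main effects,
    h2 = V_main / (V_main + V_epi + sigma2_e); unestimated epistatic variance
    counts as residual."""
    return var_main / (var_main + var_epi + sigma2_e)


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one simulated trait architecture.

    qtl entries are (genetic position cM, additive effect in trait units);
    epistatic_pairs entries are (pos_a, pos_b, effect) acting as
    effect * Z_a * Z_b.
    """

    n: int
    genome_length: float                      # cM (total)
    marker_spacing: float                     # cM
    qtl: tuple = ()
    epistatic_pairs: tuple = ()
    sigma2_e: float = 0.0
    n_chromosomes: int = 1
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        if self.marker_spacing <= 0:
            raise ValueError("marker_spacing must be > 0")
        if self.sigma2_e < 0:
            raise ValueError("sigma2_e must be >= 0")
        for q in self.qtl:
            if not 0 <= q[0] <= self.genome_length:
                raise ValueError(f"QTL position {q[0]} outside genome")
        for a, b, _ in self.epistatic_pairs:
            if not (0 <= a <= self.genome_length and 0 <= b <= self.genome_length):
                raise ValueError("epistatic pair position outside genome")

    def marker_map(self) -> MarkerMap:
        if self.n_chromosomes != 1:
            raise NotImplementedError("presets use a single chromosome")
        return evenly_spaced_map(self.genome_length, self.marker_spacing)


@dataclass
class SimulatedDataset:
    map: MarkerMap
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeVector
    design: SimDesign
    qtl_marker_index: np.ndarray          # anchor column per QTL
    var_main: float                       # realized genetic main variance
    var_epistatic: float                  # realized epistatic variance
    var_error: float                      # realized residual variance
    h2_realized: float
    h2_expected: float

    def truth_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "qtl_pos_cM": [q[0] for q in self.design.qtl],
                "effect": [q[1] for q in self.design.qtl],
                "marker_index": self.qtl_marker_index,
                "marker_id": self.map.marker_id[self.qtl_marker_index],
            }
        )


def _anchor(positions: np.ndarray, pos: float) -> int:
    """Nearest marker column; ties broken toward the lower index."""
    return int(np.argmin(np.abs(positions - pos)))


def simulate_phenotype(
    G: GenotypeMatrix, mmap: MarkerMap, design: SimDesign, seed=None
) -> tuple[PhenotypeVector, dict]:
    """y_j = sum_k a_k Z_jk + sum_(a,b) g_ab Z_ja Z_jb + e_j.

    QTL positions are anchored to the nearest marker column.  Returns the
    phenotypes and a dict of realized variance components
    (var_main, var_epistatic, var_error, h2_realized, h2_expected).
    """
    rng = np.random.default_rng(seed)
    pos = mmap.genetic_pos
    Z = G.values
    g_main = np.zeros(G.n_individuals)
    anchors = np.array(
        [_anchor(pos, q[0]) for q in design.qtl], dtype=int
    )
    for (qpos, eff), col in zip(design.qtl, anchors):
        g_main += eff * Z[:, col]
    g_epi = np.zeros(G.n_individuals)
    for pa, pb, eff in design.epistatic_pairs:
        g_epi += eff * Z[:, _anchor(pos, pa)] * Z[:, _anchor(pos, pb)]
    eps = rng.normal(0.0, np.sqrt(design.sigma2_e), size=G.n_individuals)
    y = g_main + g_epi + eps
    vm = float(np.var(g_main, ddof=1))
    ve = float(np.var(g_epi, ddof=1)) if len(design.epistatic_pairs) else 0.0
    vr = float(np.var(eps, ddof=1))
    info = {
        "anchors": anchors,
        "var_main": vm,
        "var_epistatic": ve,
        "var_error": vr,
        "h2_realized": heritability(vm, ve, vr),
        "h2_expected": heritability(
            _genetic_variance(
                np.array([q[0] for q in design.qtl]),
                np.array([q[1] for q in design.qtl]),
            )
            if design.qtl
            else 0.0,
            _expected_epistatic_variance(design),
            design.sigma2_e,
        ),
    }
    return PhenotypeVector(y, G.individual_ids), info


# ---------------------------------------------------------------------------
# analytic variance calibration
# ---------------------------------------------------------------------------


def _genetic_variance(positions: np.ndarray, effects: np.ndarray) -> float:
    """Var(sum_k a_k Z_k) = a' C a with C_hl = (1 - 2 r_hl)/2, computed
    blockwise so dense designs (10^4 QTL) stay within memory."""
    p = len(positions)
    if p == 0:
        return 0.0
    total = 0.0
    block = 2048
    for i in range(0, p, block):
        pi = positions[i : i + block]
        ai = effects[i : i + block]
        for j in range(0, p, block):
            pj = positions[j : j + block]
            aj = effects[j : j + block]
            C = f2_covariance(np.abs(pi[:, None] - pj[None, :]))
            total += ai @ C @ aj
    return float(total)


def _expected_epistatic_variance(design: SimDesign) -> float:
    # products of near-unlinked loci: Var(Z_a Z_b) = 1/4, cross terms ~ 0
    return float(sum(e**2 for *_, e in design.epistatic_pairs) / 4.0)


def _oligogenic_palette() -> tuple[np.ndarray, np.ndarray]:
    """Fixed 20-QTL palette: positions spread irregularly over 2400 cM,
    |effect| ramping ~15-fold from smallest to largest, mixed signs.  Drawn
    once from a fixed generator so presets are stable across runs."""
    rng = np.random.default_rng(20120718)
    base = np.linspace(60.0, 2340.0, 20)
    jitter = rng.uniform(-40.0, 40.0, size=20)
    positions = np.sort(base + jitter)
    mags = np.sqrt(np.linspace(1.0, 15.0, 20))     # variance ratio 1:15
    signs = rng.choice([-1.0, 1.0], size=20)
    return positions, mags * signs


def _scale_to_variance(
    positions: np.ndarray, effects: np.ndarray, target: float
) -> np.ndarray:
    v = _genetic_variance(positions, effects)
    return effects * np.sqrt(target / v)


def design_preset(
    name: str,
    scale: float = 1.0,
    n: int | None = None,
    sigma2_e: float | None = None,
    seed: int = 0,
) -> SimDesign:
    """Fully-populated SimDesign for architecture I, II, III or IV.

    ``scale`` in (0, 1] shrinks the marker count (and the polygenic QTL
    counts) while preserving the architecture; at scale 1 the marker count,
    genome length, spacing and QTL counts match the published designs.
    Oligogenic counts (20 main QTL, 20 epistatic pairs) are never reduced.
    """
    name = str(name).upper()
    if name not in {"I", "II", "III", "IV"}:
        raise ValueError(f"unknown design {name!r}")
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    n_markers = int(round(120_000 * scale)) + 1

    if name in {"I", "II", "III"}:
        genome = 2400.0
        spacing = genome / (n_markers - 1)
    else:  # IV: spacing is the architecture; genome shrinks with the markers
        spacing = 100.0
        genome = spacing * (n_markers - 1)

    qpos, qeff = _oligogenic_palette()

    if name == "I":
        eff = _scale_to_variance(qpos, qeff, MAIN_VARIANCE_I)
        qtl = tuple(zip(qpos, eff))
        pairs = _epistatic_pairs(qpos, EPISTATIC_VARIANCE_I)
        return SimDesign(
            n=n or 500, genome_length=genome, marker_spacing=spacing,
            qtl=qtl, epistatic_pairs=pairs,
            sigma2_e=20.0 if sigma2_e is None else sigma2_e,
            seed=seed, name="I",
        )

    if name == "II":
        per_cluster = max(2, int(round(500 * scale)))
        pos_list, eff_list = [], []
        for centre, parent_eff in zip(qpos, qeff):
            offs = np.linspace(-5.0, 5.0, per_cluster)
            cpos = np.clip(centre + offs, 0.0, genome)
            pos_list.append(cpos)
            eff_list.append(np.full(per_cluster, np.sign(parent_eff)))
        pos = np.concatenate(pos_list)
        eff = _scale_to_variance(pos, np.concatenate(eff_list),
                                 GENETIC_VARIANCE_II_III)
        order = np.argsort(pos)
        qtl = tuple(zip(pos[order], eff[order]))
        return SimDesign(
            n=n or 500, genome_length=genome, marker_spacing=spacing,
            qtl=qtl, sigma2_e=20.0 if sigma2_e is None else sigma2_e,
            seed=seed, name="II",
        )

    if name == "III":
        n_qtl = max(20, 2 * int(round(500 * scale)))
        pos = np.linspace(0.0, genome, n_qtl + 2)[1:-1]
        eff = np.ones(n_qtl)
        eff[n_qtl // 2 :] = -1.0            # first half +, second half -
        eff = _scale_to_variance(pos, eff, GENETIC_VARIANCE_II_III)
        qtl = tuple(zip(pos, eff))
        return SimDesign(
            n=n or 500, genome_length=genome, marker_spacing=spacing,
            qtl=qtl, sigma2_e=20.0 if sigma2_e is None else sigma2_e,
            seed=seed, name="III",
        )

    # Design IV: Design I's QTL mapped onto the expanded genome, no epistasis
    pos4 = qpos * (genome / 2400.0)
    eff4 = _scale_to_variance(pos4, qeff, MAIN_VARIANCE_I)
    qtl = tuple(zip(pos4, eff4))
    return SimDesign(
        n=n or 1000, genome_length=genome, marker_spacing=spacing,
        qtl=qtl,
        sigma2_e=(PHENOTYPIC_VARIANCE_IV - MAIN_VARIANCE_I)
        if sigma2_e is None
        else sigma2_e,
        seed=seed, name="IV",
    )


def _epistatic_pairs(qpos: np.ndarray, target_var: float) -> tuple:
    """20 pairwise interactions among the main QTL, equal magnitudes with
    mixed signs, sized so sum g^2 / 4 equals the target variance."""
    rng = np.random.default_rng(20120719)
    n_pairs = 20
    mag = np.sqrt(4.0 * target_var / n_pairs)
    pairs = []
    seen = set()
    while len(pairs) < n_pairs:
        a, b = rng.choice(len(qpos), size=2, replace=False)
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        pairs.append((qpos[a], qpos[b], mag * rng.choice([-1.0, 1.0])))
    return tuple(pairs)


def simulate_dataset(design: SimDesign, seed=None) -> SimulatedDataset:
    """Simulate map, genotypes and phenotypes for a design in one call."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    mmap = design.marker_map()
    G = simulate_f2(design.n, mmap, rng)
    y, info = simulate_phenotype(G, mmap, design, rng)
    return SimulatedDataset(
        map=mmap, genotypes=G, phenotypes=y, design=design,
        qtl_marker_index=info["anchors"],
        var_main=info["var_main"], var_epistatic=info["var_epistatic"],
        var_error=info["var_error"], h2_realized=info["h2_realized"],
        h2_expected=info["h2_expected"],
    )
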