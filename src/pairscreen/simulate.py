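"""Ground-truthed synthetic paired-gRNA screens.

The generator emulates the structure the scoring model assumes: a library
of gene pairs with 3-5 guides per gene (all-vs-all paired constructs plus
every guide paired with the non-targeting Fluc control), a triplicate
Cas9-negative day-7 baseline, triplicate screen samples at days 14 and 28,
guide-efficiency and promoter-position effects, heteroscedastic interaction
noise (spread growing with the expected lethality of the construct), and
negative-binomial sequencing counts at a configurable per-sample depth.

The true log2 fold change of a construct carrying guide i (efficiency e_i,
promoter activity m_1) against gene A and guide j (e_j, m_2) against gene B
over t days is

    lfc = ( e_i * m_1 * f_A  +  e_j * m_2 * f_B  +  e_i * e_j * eps_AB ) * t/28

with f the per-gene fitness effect and eps the pair interaction (eps < 0 =
synthetic lethal; the interaction requires both cuts, hence the e_i * e_j
factor).  The non-targeting control contributes nothing.  Baseline samples
model the Cas9-negative harvest: no fitness effects at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import (CONTROL_GENE, FLUC_SPACER, Construct, GenePair, Guide,
                      GuideLibrary, build_library)
from .quantify import (CONTEXT_3P, R1_CONTEXT_5P, R2_CONTEXT_5P, CountMatrix,
                       Sample)

__all__ = ["TrueEffects", "SimulationConfig", "simulate_truth",
           "construct_true_log2fc", "simulate_counts", "simulate_fastq",
           "simulate_screen"]

FULL_SCREEN_DAYS = 28


@dataclass
class TrueEffects:
    """Ground truth behind a simulated screen."""

    gene_fitness: dict[str, float]
    pair_interaction: dict[str, float]  # keyed by GenePair.key
    guide_efficiency: dict[str, float]
    promoter_multiplier: dict[str, float]  # slots "hU6", "sU6"
    noise_sigma0: float
    noise_sigma1: float

    def __post_init__(self):
        if any(not (0 <= e <= 1) for e in self.guide_efficiency.values()):
            raise ValueError("guide efficiencies must lie in [0, 1]")
        if any(m <= 0 for m in self.promoter_multiplier.values()):
            raise ValueError("promoter multipliers must be positive")
        if self.noise_sigma0 < 0 or self.noise_sigma1 < 0:
            raise ValueError("noise parameters must be non-negative")

    def noise_sd(self, expected_effect: float) -> float:
        """Residual s.d. as a non-decreasing function of |expected effect|."""
        return self.noise_sigma0 + self.noise_sigma1 * abs(expected_effect)

    @property
    def sl_pairs(self) -> set[str]:
        return {k for k, eps in self.pair_interaction.items() if eps < 0}

    def write_tsv(self, fitness_path, interaction_path) -> None:
        pd.DataFrame(sorted(self.gene_fitness.items()),
                     columns=["gene", "fitness"]).to_csv(
            fitness_path, sep="\t", index=False)
        pd.DataFrame(sorted(self.pair_interaction.items()),
                     columns=["gene_pair", "interaction"]).to_csv(
            interaction_path, sep="\t", index=False)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic screen.

    Defaults mirror the screening design being emulated: 3-5 guides per
    gene, triplicate baseline (Cas9-negative, day 7) and triplicate screen
    samples at days 14 and 28, sequencing at 500-fold representation per
    sample, guide efficiencies ~U(0.6, 1), a mild hU6 > sU6 promoter
    imbalance, and heteroscedastic interaction noise sd = 0.15 + 0.1*|lfc|.

    Gene fitness follows the library's composition: a non-lethal bulk
    (~N(fitness_mean, fitness_sd)) plus a ``frac_lethal_genes`` fraction of
    lethal genes (~N(lethal_fitness_mean, lethal_fitness_sd), clipped at
    0), which gives the expected-log2FC axis its multi-log2 spread; genes
    inside simulated SL pairs are always drawn from the non-lethal bulk,
    since a synthetic-lethal pair is by definition individually viable.
    """

    n_pairs: int = 200
    guides_per_gene: int = 4
    frac_sl: float = 0.05
    fitness_mean: float = 0.0
    fitness_sd: float = 0.15
    frac_lethal_genes: float = 0.2
    lethal_fitness_mean: float = -2.0
    lethal_fitness_sd: float = 0.7
    sl_effect_mean: float = -1.5
    sl_effect_sd: float = 0.0
    efficiency_low: float = 0.6
    efficiency_high: float = 1.0
    promoter_hu6: float = 1.0
    promoter_su6: float = 0.85
    noise_sigma0: float = 0.15
    noise_sigma1: float = 0.10
    baseline_sdlog: float = 0.5
    depth: float = 500.0
    nb_size: float = 50.0  # inverse dispersion; var = mu + mu^2/size
    n_baseline: int = 3
    n_screen: int = 3
    timepoints: tuple[int, ...] = (14, 28)
    baseline_day: int = 7
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not (3 <= self.guides_per_gene <= 5):
            raise ValueError("guides_per_gene must lie in [3, 5]")
        if not (0 <= self.frac_sl <= 1):
            raise ValueError("frac_sl must lie in [0, 1]")
        if not (0 <= self.frac_lethal_genes <= 1):
            raise ValueError("frac_lethal_genes must lie in [0, 1]")
        if self.depth <= 0 or self.nb_size <= 0:
            raise ValueError("depth and nb_size must be positive")
        if self.n_baseline < 1 or self.n_screen < 1:
            raise ValueError("replicate counts must be >= 1")


def _random_spacer(rng: np.random.Generator, existing: set[str]) -> str:
    while True:
        s = "".join(rng.choice(list("ACGT"), size=20))
        if s not in existing:
            existing.add(s)
            return s


def simulate_truth(cfg: SimulationConfig) -> tuple[GuideLibrary, TrueEffects]:
    """Build a library for ``cfg.n_pairs`` gene pairs and draw true effects.

    Pair i targets genes ``G{i}A`` / ``G{i}B``; the first
    ``round(frac_sl * n_pairs)`` pairs are synthetic lethal with interaction
    drawn from N(sl_effect_mean, sl_effect_sd); all other interactions are 0.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    control = Guide("Fluc", CONTROL_GENE, FLUC_SPACER, is_control=True)

    spacers: set[str] = {control.spacer}
    pair_guides: dict[GenePair, tuple[list[Guide], list[Guide]]] = {}
    for i in range(cfg.n_pairs):
        ga_name, gb_name = f"G{i:04d}A", f"G{i:04d}B"
        def mk(gene):
            return [Guide(f"{gene}_g{j+1}", gene,
                          _random_spacer(rng, spacers))
                    for j in range(cfg.guides_per_gene)]
        pair_guides[GenePair(ga_name, gb_name)] = (mk(ga_name), mk(gb_name))
    lib = build_library(pair_guides, control)

    n_sl = round(cfg.frac_sl * cfg.n_pairs)
    sl_keys = sorted(lib.pairs)[:n_sl]
    sl_genes = {g for k in sl_keys
                for g in (lib.pairs[k].gene_a, lib.pairs[k].gene_b)}

    genes = sorted({g.gene for g in lib.guides.values() if not g.is_control})
    fitness = {}
    for gene in genes:
        lethal = (gene not in sl_genes
                  and rng.random() < cfg.frac_lethal_genes)
        if lethal:
            fitness[gene] = min(rng.normal(cfg.lethal_fitness_mean,
                                           cfg.lethal_fitness_sd), 0.0)
        else:
            fitness[gene] = rng.normal(cfg.fitness_mean, cfg.fitness_sd)
    interaction = {}
    for i, key in enumerate(sorted(lib.pairs)):
        if i < n_sl:
            eps = rng.normal(cfg.sl_effect_mean, cfg.sl_effect_sd)
            interaction[key] = min(eps, -1e-9)  # SL pairs stay negative
        else:
            interaction[key] = 0.0
    efficiency = {g.guide_id: (1.0 if g.is_control else
                               float(rng.uniform(cfg.efficiency_low,
                                                 cfg.efficiency_high)))
                  for g in sorted(lib.guides.values(),
                                  key=lambda g: g.guide_id)}
    eff = TrueEffects(
        gene_fitness=fitness, pair_interaction=interaction,
        guide_efficiency=efficiency,
        promoter_multiplier={"hU6": cfg.promoter_hu6,
                             "sU6": cfg.promoter_su6},
        noise_sigma0=cfg.noise_sigma0, noise_sigma1=cfg.noise_sigma1)
    return lib, eff


def construct_true_log2fc(lib: GuideLibrary, eff: TrueEffects,
                          construct: Construct | str,
                          timepoint_days: int) -> float:
    """Noise-free true log2FC of one construct after ``timepoint_days``."""
    if isinstance(construct, str):
        try:
            construct = lib.constructs[construct]
        except KeyError:
            raise ValueError(f"unknown construct {construct!r}") from None
    elif construct.construct_id not in lib.constructs:
        raise ValueError(f"unknown construct {construct.construct_id!r}")

    scale = timepoint_days / FULL_SCREEN_DAYS
    total = 0.0
    slot_guides = [("hU6", lib.guide(construct.hu6_guide)),
                   ("sU6", lib.guide(construct.su6_guide))]
    effs = []
    for slot, guide in slot_guides:
        if guide.is_control:
            effs.append(None)
            continue
        e = eff.guide_efficiency[guide.guide_id]
        m = eff.promoter_multiplier[slot]
        total += e * m * eff.gene_fitness[guide.gene]
        effs.append(e)
    if construct.kind == "paired":
        a, b = (lib.guide(construct.hu6_guide).gene,
                lib.guide(construct.su6_guide).gene)
        eps = eff.pair_interaction[GenePair(a, b).key]
        total += effs[0] * effs[1] * eps
    return total * scale


def _sample_plan(cfg: SimulationConfig) -> list[Sample]:
    samples = [Sample(f"base_r{r+1}", "baseline", r + 1, cfg.baseline_day)
               for r in range(cfg.n_baseline)]
    for day in cfg.timepoints:
        samples += [Sample(f"d{day}_r{r+1}", "screen", r + 1, day)
                    for r in range(cfg.n_screen)]
    return samples


def simulate_counts(lib: GuideLibrary, eff: TrueEffects,
                    cfg: SimulationConfig) -> CountMatrix:
    """Negative-binomial counts for the full sample plan.

    One log-normal baseline abundance per construct is shared by every
    sample; screen samples multiply it by 2^(true lfc + noise) with the
    heteroscedastic noise drawn per construct per sample, then all samples
    are sequenced to ``depth * n_constructs`` expected reads.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    order = sorted(lib.constructs)
    n = len(order)
    abundance = rng.lognormal(mean=0.0, sigma=cfg.baseline_sdlog, size=n)

    samples = _sample_plan(cfg)
    true_lfc = {day: np.array([construct_true_log2fc(lib, eff, c, day)
                               for c in order])
                for day in cfg.timepoints}
    total_reads = cfg.depth * n
    cols = {}
    for s in samples:
        if s.role == "baseline":
            w = abundance
        else:
            lfc = true_lfc[s.timepoint_days]
            sd = eff.noise_sigma0 + eff.noise_sigma1 * np.abs(lfc)
            noise = rng.normal(0.0, 1.0, size=n) * sd
            w = abundance * np.exp2(lfc + noise)
        mu = total_reads * w / w.sum()
        # NB(mean mu, size k): p = k/(k+mu)
        p = cfg.nb_size / (cfg.nb_size + mu)
        cols[s.sample_id] = rng.negative_binomial(cfg.nb_size, p)
    df = pd.DataFrame(cols, index=pd.Index(order, name="construct_id"),
                      dtype=np.int64)
    return CountMatrix(df, samples, {s.sample_id: 0 for s in samples})


def simulate_fastq(counts: CountMatrix, lib: GuideLibrary, out_r1, out_r2,
                   seed: int = 0, sample_id: str | None = None) -> int:
    """Write paired FASTQ for one sample of a count matrix.

    Each construct contributes exactly its count in read pairs; read 1
    carries the hU6 spacer and read 2 the sU6 spacer, both embedded at the
    fixed offset inside the constant vector context.  Read order is
    shuffled (seeded).  Returns the number of read pairs written.
    """
    if sample_id is None:
        if len(counts.samples) != 1:
            raise ValueError("sample_id required for a multi-sample matrix")
        sample_id = counts.samples[0].sample_id
    col = counts.counts[sample_id]
    reps = np.repeat(np.arange(len(col)), col.to_numpy())
    rng = np.random.default_rng(seed)
    rng.shuffle(reps)
    ids = col.index.to_numpy()
    total = 0
    with open(out_r1, "w") as f1, open(out_r2, "w") as f2:
        for k, ci in enumerate(reps):
            c = lib.constructs[ids[ci]]
            s1 = R1_CONTEXT_5P + lib.guide(c.hu6_guide).spacer + CONTEXT_3P
            s2 = R2_CONTEXT_5P + lib.guide(c.su6_guide).spacer + CONTEXT_3P
            name = f"@{sample_id}:{k} {ids[ci]}"
            f1.write(f"{name}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"{name}/2\n{s2}\n+\n{'I' * len(s2)}\n")
            total += 1
    return total


def simulate_screen(cfg: SimulationConfig
                    ) -> tuple[GuideLibrary, TrueEffects, CountMatrix]:
    """Convenience wrapper: truth plus counts in one call."""
    lib, eff = simulate_truth(cfg)
    return lib, eff, simulate_counts(lib, eff, cfg)
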