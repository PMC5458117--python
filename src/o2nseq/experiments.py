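"""Self-contained spike-in mixture experiments used for benchmarking.

These functions generate a synthetic reference, spike minor alleles at known
sites, push the simulated library through the pipeline and score the calls
against the spiked truth.  Problem sizes default to desk-scale versions of
the two mixture designs the method targets: a 1:100 mixture read to ~800x
consensus depth, and a 1:1,000-style ultralow mixture read to ~20,000x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import GoldStandard, sensitivity_fpr
from .pipeline import PipelineParams, run_from_consensus, run_from_pairs
from .simulate import (
    LibraryConfig,
    TruthVariant,
    random_reference,
    simulate_consensus_reads,
    simulate_pairs,
)

_ALT = {"A": "C", "C": "A", "G": "T", "T": "G"}


def expected_usable_per_pair(config: LibraryConfig, min_overlap: int = 8) -> float:
    """Mean usable consensus bases yielded per generated right-on pair.

    Small analytic yield model used to size libraries for a target depth:
    a fragment of length F yields F - 6 usable bases (3-bp trim each side)
    when the adaptor is locatable in a mate without junk carryover
    (F <= read_length - 5 - min_overlap) and the pair survives the
    <2-copy-mismatch rule, whose failure is Poisson with rate 2e per
    dual-covered base.
    """
    e = config.error_rate
    total, count = 0.0, 0
    for flen in range(config.frag_min, config.frag_max + 1):
        count += 1
        if flen > config.read_length - 5 - min_overlap:
            continue  # adaptor cannot be located without junk in the target
        lam = 2.0 * e * max(flen - 3, 0)
        p_keep = np.exp(-lam) * (1.0 + lam)
        total += p_keep * max(flen - 6, 0)
    return (total / count) * config.right_on_fraction


def pairs_for_depth(config: LibraryConfig, target_depth: float) -> int:
    yield_per_pair = expected_usable_per_pair(config)
    return int(np.ceil(target_depth * len(config.reference.sequence) / yield_per_pair))


def _spike_sites(
    reference, n_sites: int, allele_fraction: float, rng: np.random.Generator, margin: int = 200
) -> list[TruthVariant]:
    L = len(reference.sequence)
    positions = rng.choice(np.arange(margin, L - margin), size=n_sites, replace=False)
    return [
        TruthVariant(
            int(p),
            reference.sequence[int(p)],
            _ALT[reference.sequence[int(p)]],
            allele_fraction,
        )
        for p in sorted(positions)
    ]


@dataclass
class MixtureResult:
    sensitivity: float
    fpr: float | None
    n_sites: int
    n_calls: int
    n_true_positive: int
    n_false_positive: int
    mean_depth: float

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.sensitivity

    @property
    def fpr_pct(self) -> float | None:
        return None if self.fpr is None else 100.0 * self.fpr


def _score(result, gold: GoldStandard) -> MixtureResult:
    sens, fpr = sensitivity_fpr(result.calls, gold)
    keys = gold.site_keys()
    eligible = [c for c in result.calls if c.position not in gold.excluded_positions()]
    tp = len({(c.position, c.alt_base) for c in eligible} & keys)
    fp = sum(1 for c in eligible if (c.position, c.alt_base) not in keys)
    depths = result.depth_vector()
    interior = depths[depths > 0]
    return MixtureResult(
        sensitivity=sens if sens is not None else 0.0,
        fpr=fpr,
        n_sites=len(gold.sites),
        n_calls=len(eligible),
        n_true_positive=tp,
        n_false_positive=fp,
        mean_depth=float(interior.mean()) if interior.size else 0.0,
    )


def run_low_freq_mixture(
    seed: int,
    ref_length: int = 10_000,
    n_sites: int = 100,
    allele_fraction: float = 0.0099,
    target_depth: float = 800.0,
    quality: int = 30,
    min_cs: int = 1,
    min_maf: float = 0.0,
    full_output: bool = False,
):
    """1:100-style mixture: spiked ~1% sites, full raw-read pipeline.

    Simulates o2n pairs at Q30 (per-base error 1e-3), runs adaptor splitting,
    quality filtering, per-pair consensus, mapping and calling, then scores
    sensitivity/FPR at the requested distinct-CS level.  With ``full_output``
    the underlying :class:`~o2nseq.pipeline.PipelineResult` and gold standard
    are returned alongside the score.
    """
    rng = np.random.default_rng(seed)
    reference = random_reference(ref_length, rng)
    sites = _spike_sites(reference, n_sites, allele_fraction, rng)
    config = LibraryConfig(
        reference=reference,
        variants=sites,
        quality=quality,
        seed=int(rng.integers(2**31)),
    )
    config.n_pairs = pairs_for_depth(config, target_depth)
    params = PipelineParams(min_cs=min_cs, min_maf=min_maf)
    pairs = (pair for pair, _ in simulate_pairs(config))
    result = run_from_pairs(pairs, reference, params)
    gold = GoldStandard(sites=sites)
    score = _score(result, gold)
    if full_output:
        return score, result, gold
    return score


def run_ultralow_mixture(
    seed: int,
    ref_length: int = 5386,
    allele_fractions: tuple[float, ...] = (6.9e-4, 8.0e-4),
    target_depth: float = 20_000.0,
    raw_error: float = 1e-3,
    min_cs: int = 6,
    min_maf: float = 0.000345,
) -> MixtureResult:
    """1:1,000-style ultralow mixture at consensus level.

    Consensus reads are generated directly, with each base passed through the
    dual-copy error channel (coincident-error rate ``raw_error**2 / 3``), and
    mapped/called under the n x CS criterion with the half-theoretical
    frequency filter.
    """
    rng = np.random.default_rng(seed)
    reference = random_reference(ref_length, rng)
    positions = rng.choice(
        np.arange(200, ref_length - 200), size=len(allele_fractions), replace=False
    )
    sites = [
        TruthVariant(int(p), reference.sequence[int(p)], _ALT[reference.sequence[int(p)]], af)
        for p, af in zip(sorted(positions), allele_fractions)
    ]
    config = LibraryConfig(
        reference=reference,
        variants=sites,
        seed=int(rng.integers(2**31)),
    )
    mean_usable = np.mean(
        [f - 6 for f in range(config.frag_min, config.frag_max + 1)]
    )
    n_reads = int(np.ceil(target_depth * ref_length / mean_usable))
    cs_error = raw_error**2 / 3.0
    reads = (
        cs
        for cs, _ in simulate_consensus_reads(
            config, n_reads, cs_error, rng=np.random.default_rng(config.seed)
        )
    )
    params = PipelineParams(min_cs=min_cs, min_maf=min_maf)
    result = run_from_consensus(reads, reference, params)
    return _score(result, GoldStandard(sites=sites))
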