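"""Seeded synthetic case/control GWAS generator with LD-block structure.

The generator emulates the two features of real GWAS data the training
algorithm must cope with: genetic linkage and planted causal signal. SNPs
come in blocks; within a block, each proxy SNP copies the block's first
(tag) SNP allele-wise with probability q = sqrt(within_block_r2) and
otherwise draws a fresh allele at the block's minor-allele frequency, so
the tag-proxy genotype correlation is q and the tag-proxy r^2 hits the
requested target (proxy-proxy r^2 is the square of the target — the star
structure of a copy model). Blocks are separated by more than the 1 Mb
linkage window, so the distance rule of attribute pruning is exercised in
both directions.

Disease status is driven by the tag SNPs of the designated causal blocks
through penetrance triples (Pr(case | genotype 0/1/2)); with several causal
blocks the per-block contributions combine additively on the log-odds
scale (the standard multiplicative-odds multi-locus model), so each tag's
stated triple is approximately its marginal penetrance. Subjects are
sampled until the case and control quotas fill, which fixes class
unbalance exactly. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gwas_data import CASE, CONTROL, MISSING, GenotypeDataset, SnpInfo

_CANDIDATE_CHUNK = 256  # fixed so that generation is seed-deterministic


class GenerationError(RuntimeError):
    """Raised when the case/control quotas cannot be filled."""


@dataclass(frozen=True)
class SimSpec:
    """Full description of one synthetic dataset."""

    n_cases: int
    n_controls: int
    n_blocks: int
    block_size: int
    within_block_r2: float
    block_span_bp: int = 500_000
    causal_blocks: tuple = ()  # (block_index, (p_case|0, p_case|1, p_case|2))
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.0
    seed: int = 0
    inter_block_gap_bp: int = 2_000_000
    chromosome: str = "1"

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not 0 <= self.within_block_r2 <= 1:
            raise ValueError("within_block_r2 must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie in (0, 0.5]")
        for bi, triple in self.causal_blocks:
            if not 0 <= bi < self.n_blocks:
                raise ValueError(f"causal block index {bi} out of range")
            if len(triple) != 3 or not all(0 <= p <= 1 for p in triple):
                raise ValueError("penetrance triples must be three probabilities")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    causal_snp_ids: list[str]
    tag_snp_ids: list[str]  # tag of every block, causal or not
    block_of: dict  # snp_id -> block index
    realized_block_r2: dict = field(default_factory=dict)  # block -> mean tag-proxy r^2


def _snp_id(block: int, i: int) -> str:
    return f"blk{block:03d}_snp{i:02d}"


def _block_genotypes(
    rng: np.random.Generator, m: int, maf: float, block_size: int, q: float
) -> np.ndarray:
    """Genotype codes (m, block_size) for one block; column 0 is the tag."""
    tag_alleles = rng.random((m, 2)) < maf  # True = minor allele
    out = np.empty((m, block_size), dtype=np.int8)
    out[:, 0] = 2 - tag_alleles.sum(axis=1)
    if block_size > 1:
        k = block_size - 1
        copy = rng.random((m, 2, k)) < q
        fresh = rng.random((m, 2, k)) < maf
        proxy = np.where(copy, tag_alleles[:, :, None], fresh)
        out[:, 1:] = 2 - proxy.sum(axis=1)
    return out


def simulate(spec: SimSpec) -> tuple[GenotypeDataset, SimTruth]:
    """Generate one dataset and its ground truth, deterministically."""
    ss = np.random.SeedSequence(spec.seed)
    rng_geno, rng_label, rng_miss = (np.random.default_rng(c) for c in ss.spawn(3))
    mafs = rng_geno.uniform(*spec.maf_range, size=spec.n_blocks)
    q = float(np.sqrt(spec.within_block_r2))
    penetrance = {bi: np.asarray(triple, dtype=float) for bi, triple in spec.causal_blocks}

    n_target = spec.n_cases + spec.n_controls
    quotas = {CASE: spec.n_cases, CONTROL: spec.n_controls}
    kept_rows: list[np.ndarray] = []
    kept_labels: list[int] = []
    max_candidates = 200 * n_target
    seen = 0
    while quotas[CASE] > 0 or quotas[CONTROL] > 0:
        if seen >= max_candidates:
            raise GenerationError(
                f"case/control quotas unreachable after {seen} candidates"
            )
        blocks = [
            _block_genotypes(rng_geno, _CANDIDATE_CHUNK, mafs[b], spec.block_size, q)
            for b in range(spec.n_blocks)
        ]
        G = np.concatenate(blocks, axis=1)
        if penetrance:
            # multiplicative odds across causal blocks
            logit_sum = np.zeros(_CANDIDATE_CHUNK)
            for b in penetrance:
                p = np.clip(penetrance[b][blocks[b][:, 0]], 1e-12, 1 - 1e-12)
                logit_sum += np.log(p / (1 - p))
            p_case = 1.0 / (1.0 + np.exp(-logit_sum))
        else:
            p_case = np.full(_CANDIDATE_CHUNK, 0.5)
        labels = np.where(rng_label.random(_CANDIDATE_CHUNK) < p_case, CASE, CONTROL)
        seen += _CANDIDATE_CHUNK
        for i in range(_CANDIDATE_CHUNK):
            lab = int(labels[i])
            if quotas[lab] > 0:
                quotas[lab] -= 1
                kept_rows.append(G[i])
                kept_labels.append(lab)
            if quotas[CASE] == 0 and quotas[CONTROL] == 0:
                break

    genotypes = np.vstack(kept_rows)
    labels_arr = np.array(kept_labels, dtype=np.int8)
    if spec.missing_rate > 0:
        mask = rng_miss.random(genotypes.shape) < spec.missing_rate
        genotypes = np.where(mask, np.int8(MISSING), genotypes)

    snps: list[SnpInfo] = []
    block_of: dict[str, int] = {}
    stride = spec.block_span_bp + spec.inter_block_gap_bp
    for b in range(spec.n_blocks):
        start = 1 + b * stride
        for i in range(spec.block_size):
            if spec.block_size > 1:
                pos = start + round(i * spec.block_span_bp / (spec.block_size - 1))
            else:
                pos = start
            sid = _snp_id(b, i)
            snps.append(SnpInfo(sid, spec.chromosome, pos))
            block_of[sid] = b

    ds = GenotypeDataset(
        genotypes=genotypes,
        snps=snps,
        labels=labels_arr,
        subject_ids=[f"subj{i:05d}" for i in range(n_target)],
    )
    truth = SimTruth(
        causal_snp_ids=[_snp_id(b, 0) for b, _ in spec.causal_blocks],
        tag_snp_ids=[_snp_id(b, 0) for b in range(spec.n_blocks)],
        block_of=block_of,
    )
    # realized LD: mean tag-proxy r^2 per block, on the final matrix
    from .ensemble import squared_correlation

    all_rows = np.arange(ds.n_subjects)
    for b in range(spec.n_blocks):
        tag_col = ds.snp_index(_snp_id(b, 0))
        r2s = [
            squared_correlation(ds, tag_col, ds.snp_index(_snp_id(b, i)), all_rows)
            for i in range(1, spec.block_size)
        ]
        truth.realized_block_r2[b] = float(np.mean(r2s)) if r2s else 1.0
    return ds, truth


#: Parameters of the repository's canonical test dataset: 1,000 subjects
#: (400 cases / 600 controls), 50 blocks of 10 SNPs, tag-proxy r^2 0.6,
#: three causal blocks with strong-to-moderate penetrance triples, 1%
#: missing genotypes.
STANDARD_FIXTURE_SEED = 20120


def standard_fixture_spec(seed: int = STANDARD_FIXTURE_SEED) -> SimSpec:
    return SimSpec(
        n_cases=400,
        n_controls=600,
        n_blocks=50,
        block_size=10,
        within_block_r2=0.6,
        causal_blocks=(
            (5, (0.85, 0.55, 0.25)),
            (25, (0.75, 0.50, 0.30)),
            (45, (0.70, 0.50, 0.35)),
        ),
        maf_range=(0.2, 0.4),
        missing_rate=0.01,
        seed=seed,
    )


def standard_fixture(seed: int = STANDARD_FIXTURE_SEED) -> tuple[GenotypeDataset, SimTruth]:
    """The canonical 1,000 x 500 test dataset (see module docstring)."""
    return simulate(standard_fixture_spec(seed))
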