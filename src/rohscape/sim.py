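"""Synthetic SNP-array data with known ground truth.

The generator emulates the study design the package targets: two diverged
lines genotyped on a ~50K chip laid over 18 autosomes (~54 kb mean marker
spacing), with per-individual autozygous tracts spanning the three ROH
length classes, genotyping error and missingness, and an additive phenotype
with age/batch covariates.  Every stage of the analysis can therefore be
verified against planted truth.

Model choices:

* **Divergence** — Balding-Nichols: ancestral allele frequencies are uniform
  on [0.05, 0.95] and each population's frequency is drawn
  ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, so the Weir-Cockerham FST estimator has
  a known target ``F``.  Genotypes are Hardy-Weinberg within population.
* **Autozygosity** — a planted tract overwrites an individual's genotypes
  with homozygous calls from one sampled haplotype (no hets).  Tracts are
  either per-individual (random locations) or population-frequency tracts at
  a fixed, shared locus (for hotspot scenarios: carriers share one
  haplotype, as identity-by-descent implies).
* **Genotyping error** — hom-to-het flips only: the error mode the ROH
  caller's one-heterozygote window allowance exists to absorb.
* **Phenotype** — ``y = mu + beta * dosage + gamma_age * age + batch offset
  + N(0, sd^2)`` with ages uniform integers and batches round-robin.

All randomness flows from a single mandatory seed through numpy's PCG64
generator; outputs are bit-identical across runs for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, make_markers, make_samples

RNG_ALGORITHM = "numpy.random.Generator(PCG64)"


@dataclass(frozen=True)
class RohPlanItem:
    """One planting rule: a tract length plus either a per-individual count
    or a population carrier frequency at a fixed shared locus."""

    length_bp: int
    count: Optional[int] = None
    freq: Optional[float] = None
    chrom: Optional[str] = None
    start_bp: Optional[int] = None

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if (self.count is None) == (self.freq is None):
            raise ValueError("specify exactly one of count or freq")
        if self.freq is not None and not 0.0 < self.freq <= 1.0:
            raise ValueError("freq must be in (0, 1]")


#: Default plan: one tract per ROH length class per individual.  The short
#: class is represented by 4 Mb: at chip density (~54 kb/SNP) the
#: false-positive SNP-count threshold makes tracts much below ~3 Mb
#: undetectable by construction.
DEFAULT_ROH_PLAN: tuple[RohPlanItem, ...] = (
    RohPlanItem(4_000_000, count=1),
    RohPlanItem(7_000_000, count=1),
    RohPlanItem(12_000_000, count=1),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: two lines, 18 autosomes, chip-like density."""

    seed: int
    n_pops: int = 2
    n_per_pop: int = 100
    n_chrom: int = 18
    chrom_length_bp: int = 136_000_000
    n_snps_per_chrom: int = 2_524
    fst_target: float = 0.093
    roh_plan: tuple[RohPlanItem, ...] = DEFAULT_ROH_PLAN
    miss_rate: float = 0.01
    err_rate: float = 0.002

    def __post_init__(self):
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must be in [0, 1)")
        for name in ("miss_rate", "err_rate"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.n_snps_per_chrom < 2:
            raise ValueError("n_snps_per_chrom must be >= 2")
        if self.n_pops < 1 or self.n_per_pop < 1 or self.n_chrom < 1:
            raise ValueError("population/chromosome counts must be >= 1")
        for item in self.roh_plan:
            if item.length_bp > self.chrom_length_bp:
                raise ValueError(
                    f"planned tract of {item.length_bp} bp exceeds chromosome "
                    f"length {self.chrom_length_bp}"
                )


@dataclass
class SimTruth:
    """Ground truth accumulated across the generation stages."""

    config: SimConfig
    pop_allele_freqs: pd.DataFrame  # marker_id + one frequency column per pop
    ancestral_freqs: np.ndarray
    planted_segments: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "chrom", "start_bp", "end_bp"]
        )
    )
    beta_snp: Optional[float] = None
    covariate_effects: Optional[dict] = None
    noise_sd: Optional[float] = None
    mean_dosage_samples: tuple[str, ...] = ()
    rng_algorithm: str = RNG_ALGORITHM


def _unique_sorted_positions(rng, n: int, length_bp: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length_bp + 1, size=n))
    while len(pos) < n:
        extra = rng.integers(1, length_bp + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos[:n])


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Clean Hardy-Weinberg genotypes for the configured populations.

    No missingness, error or planted tracts here — those are layered on by
    :func:`plant_autozygosity` (see :func:`simulate_dataset`).
    """
    rng = np.random.default_rng(config.seed)
    chroms, positions = [], []
    for c in range(1, config.n_chrom + 1):
        pos = _unique_sorted_positions(rng, config.n_snps_per_chrom, config.chrom_length_bp)
        chroms += [str(c)] * len(pos)
        positions.append(pos)
    positions = np.concatenate(positions)
    n_markers = len(positions)
    markers = make_markers(chroms, positions)

    p_anc = rng.uniform(0.05, 0.95, size=n_markers)
    f = config.fst_target
    pop_freqs = {}
    for k in range(config.n_pops):
        if f > 0:
            pk = rng.beta(p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f)
            pk = np.clip(pk, 1e-6, 1 - 1e-6)
        else:
            pk = p_anc.copy()
        pop_freqs[f"pop{k + 1}"] = pk

    blocks, sample_ids, pops, sexes = [], [], [], []
    for k in range(config.n_pops):
        pk = pop_freqs[f"pop{k + 1}"]
        blocks.append(
            rng.binomial(2, pk[None, :], size=(config.n_per_pop, n_markers)).astype(
                np.int8
            )
        )
        sample_ids += [f"pop{k + 1}_{i + 1:04d}" for i in range(config.n_per_pop)]
        pops += [f"pop{k + 1}"] * config.n_per_pop
        sexes += ["female" if i % 2 else "male" for i in range(config.n_per_pop)]
    calls = np.concatenate(blocks, axis=0)
    matrix = GenotypeMatrix(calls, make_samples(sample_ids, pops, sexes), markers)

    freq_frame = pd.DataFrame({"marker_id": matrix.markers["marker_id"]})
    for pop, pk in pop_freqs.items():
        freq_frame[pop] = pk
    truth = SimTruth(config=config, pop_allele_freqs=freq_frame, ancestral_freqs=p_anc)
    return matrix, truth


def _merge_intervals(frame: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping planted tracts per (sample, chrom)."""
    if frame.empty:
        return frame
    rows = []
    for (sid, chrom), sub in frame.groupby(["sample_id", "chrom"], sort=False):
        ivs = sorted(zip(sub["start_bp"], sub["end_bp"]))
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        rows += [(sid, chrom, s, e) for s, e in merged]
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp", "end_bp"])


def plant_autozygosity(
    matrix: GenotypeMatrix,
    roh_plan: Sequence[RohPlanItem],
    seed: int,
    *,
    err_rate: float = 0.0,
    miss_rate: float = 0.0,
    truth: Optional[SimTruth] = None,
    chrom_length_bp: Optional[int] = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Overwrite genotypes with homozygous tracts; then apply error/missing.

    Per-individual error (hom->het flips) and missingness apply genome-wide,
    inside and outside tracts.  Overlapping tracts in one individual are
    merged in the recorded truth.  When *truth* (from
    :func:`simulate_genotypes`) is given, haplotypes are drawn from the
    population allele frequencies; otherwise from sample frequencies.
    """
    rng = np.random.default_rng(seed)
    calls = matrix.calls.copy()
    markers = matrix.markers
    chrom_labels = list(dict.fromkeys(markers["chrom"]))
    pos_by_chrom = {
        str(c): (sub.index.to_numpy(), sub["pos_bp"].to_numpy())
        for c, sub in markers.groupby("chrom", sort=False)
    }
    span_by_chrom = {
        c: (chrom_length_bp or int(pos_by_chrom[c][1][-1])) for c in pos_by_chrom
    }

    if truth is not None:
        pop_freq_cols = truth.pop_allele_freqs.set_index("marker_id")
        freq_of = {
            pop: pop_freq_cols.loc[markers["marker_id"], pop].to_numpy()
            for pop in pop_freq_cols.columns
        }
    else:
        sample_freq = matrix.allele2_freq()
        freq_of = {pop: np.nan_to_num(sample_freq, nan=0.5) for pop in matrix.populations}

    planted_rows = []

    def overwrite(i: int, chrom: str, start: int, length: int, hap: np.ndarray, lo: int):
        end = start + length - 1
        idx, pos = pos_by_chrom[chrom]
        a = np.searchsorted(pos, start, side="left")
        b = np.searchsorted(pos, end, side="right")
        calls[i, idx[a:b]] = 2 * hap[a - lo : b - lo]
        planted_rows.append(
            (str(matrix.sample_ids.iat[i]), chrom, int(start), int(end))
        )

    pops = matrix.samples["population"].to_numpy()
    for item in roh_plan:
        if item.count is not None:
            for i in range(matrix.n_samples):
                p = freq_of.get(str(pops[i]), next(iter(freq_of.values())))
                for _ in range(item.count):
                    chrom = item.chrom or str(
                        chrom_labels[rng.integers(0, len(chrom_labels))]
                    )
                    span = span_by_chrom[chrom]
                    max_start = max(1, span - item.length_bp + 1)
                    start = (
                        item.start_bp
                        if item.start_bp is not None
                        else int(rng.integers(1, max_start + 1))
                    )
                    idx, pos = pos_by_chrom[chrom]
                    a = np.searchsorted(pos, start, side="left")
                    b = np.searchsorted(pos, start + item.length_bp - 1, side="right")
                    hap = (rng.random(b - a) < p[idx[a:b]]).astype(np.int8)
                    overwrite(i, chrom, start, item.length_bp, hap, a)
        else:
            chrom = item.chrom or str(chrom_labels[rng.integers(0, len(chrom_labels))])
            span = span_by_chrom[chrom]
            max_start = max(1, span - item.length_bp + 1)
            start = (
                item.start_bp
                if item.start_bp is not None
                else int(rng.integers(1, max_start + 1))
            )
            idx, pos = pos_by_chrom[chrom]
            a = np.searchsorted(pos, start, side="left")
            b = np.searchsorted(pos, start + item.length_bp - 1, side="right")
            p_any = next(iter(freq_of.values()))
            shared_hap = (rng.random(b - a) < p_any[idx[a:b]]).astype(np.int8)
            carriers = rng.random(matrix.n_samples) < item.freq
            for i in np.flatnonzero(carriers):
                overwrite(i, chrom, start, item.length_bp, shared_hap, a)

    # genotyping error: hom -> het flips
    if err_rate > 0:
        hom = (calls == 0) | (calls == 2)
        flip = hom & (rng.random(calls.shape) < err_rate)
        calls[flip] = 1
    # missingness
    if miss_rate > 0:
        calls[rng.random(calls.shape) < miss_rate] = MISSING

    planted = _merge_intervals(
        pd.DataFrame(planted_rows, columns=["sample_id", "chrom", "start_bp", "end_bp"])
    )
    if truth is None:
        truth = SimTruth(
            config=None,  # type: ignore[arg-type]
            pop_allele_freqs=pd.DataFrame({"marker_id": markers["marker_id"]}),
            ancestral_freqs=np.array([]),
        )
    new_truth = replace(truth, planted_segments=planted)
    out = GenotypeMatrix(calls, matrix.samples, markers, sort=False, validate=False)
    return out, new_truth


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Full generator: HWE genotypes, planted tracts, error, missingness."""
    matrix, truth = simulate_genotypes(config)
    return plant_autozygosity(
        matrix,
        config.roh_plan,
        seed=config.seed + 1,
        err_rate=config.err_rate,
        miss_rate=config.miss_rate,
        truth=truth,
        chrom_length_bp=config.chrom_length_bp,
    )


def simulate_phenotypes(
    matrix: GenotypeMatrix,
    focal_marker: str,
    beta: float,
    cov_effects: tuple[float, Sequence[float]] = (0.05, (0.0, 1.0, -1.0)),
    noise_sd: float = 3.0,
    seed: int = 0,
    *,
    mu: float = 100.0,
    age_range: tuple[int, int] = (150, 250),
) -> tuple[pd.DataFrame, SimTruth, dict]:
    """Additive single-SNP phenotype with age and batch covariates.

    ``cov_effects`` is ``(gamma_age, batch_offsets)``; batches are assigned
    round-robin over the offset list.  An individual missing the focal
    genotype still gets a phenotype, computed at the population mean dosage
    and flagged in the returned truth.
    """
    rng = np.random.default_rng(seed)
    hits = np.flatnonzero((matrix.markers["marker_id"] == focal_marker).to_numpy())
    if hits.size == 0:
        raise KeyError(f"focal marker {focal_marker!r} not in matrix")
    j = int(hits[0])
    code = matrix.calls[:, j].astype(float)
    miss = code == MISSING
    mean_dose = float(code[~miss].mean()) if (~miss).any() else 1.0
    code[miss] = mean_dose

    gamma_age, batch_offsets = cov_effects
    batch_offsets = list(batch_offsets)
    n = matrix.n_samples
    ages = rng.integers(age_range[0], age_range[1] + 1, size=n).astype(float)
    batch_idx = np.arange(n) % len(batch_offsets)
    offsets = np.asarray(batch_offsets, dtype=float)[batch_idx]
    y = mu + beta * code + gamma_age * ages + offsets + rng.normal(0.0, noise_sd, size=n)

    pheno = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids.astype(str),
            "trait": y,
            "age": ages,
            "batch": [f"b{k + 1}" for k in batch_idx],
        }
    )
    truth = SimTruth(
        config=None,  # type: ignore[arg-type]
        pop_allele_freqs=pd.DataFrame({"marker_id": matrix.markers["marker_id"]}),
        ancestral_freqs=np.array([]),
        beta_snp=beta,
        covariate_effects={"age": gamma_age, "batch": batch_offsets},
        noise_sd=noise_sd,
        mean_dosage_samples=tuple(matrix.sample_ids[miss].astype(str)),
    )
    extras = {"mu": mu, "focal_index": j, "mean_dosage": mean_dose}
    return pheno, truth, extras


# ---------------------------------------------------------------------------
# Truth-based evaluation of ROH recovery
# ---------------------------------------------------------------------------

def evaluate_recovery(
    planted: pd.DataFrame,
    called: pd.DataFrame,
    matrix: GenotypeMatrix,
    max_inward_intervals: int = 1,
) -> pd.DataFrame:
    """Score called segments against planted tracts.

    A planted tract is *recovered* when called segments overlapping it cover
    its markers up to at most ``max_inward_intervals`` *informative* markers
    missed at each end.  Informative means homozygous-called: a marker whose
    call is heterozygous (a simulated genotyping error) or missing carries no
    evidence of autozygosity, so a boundary can only be located to the
    nearest homozygous-called marker.  Outward extension into flanking
    markers is reported (``overrun_left/right`` in marker intervals) but not
    scored as error, by the same resolution argument: the caller's
    heterozygote allowance deliberately absorbs isolated flanking hets.
    Raw marker-interval deficits are also reported.
    """
    pos_by_chrom = {
        str(c): (sub.index.to_numpy(), sub["pos_bp"].to_numpy())
        for c, sub in matrix.markers.groupby("chrom", sort=False)
    }
    sample_row = {str(s): i for i, s in enumerate(matrix.sample_ids)}
    called_by = {}
    if not called.empty:
        for (sid, chrom), sub in called.groupby(["sample_id", "chrom"], sort=False):
            called_by[(str(sid), str(chrom))] = sub
    rows = []
    for t in planted.itertuples():
        col_idx, pos = pos_by_chrom[str(t.chrom)]
        t_lo = int(np.searchsorted(pos, t.start_bp, side="left"))
        t_hi = int(np.searchsorted(pos, t.end_bp, side="right")) - 1
        sub = called_by.get((str(t.sample_id), str(t.chrom)))
        rec = False
        start_deficit = end_deficit = np.nan
        info_start_deficit = info_end_deficit = np.nan
        overrun_l = overrun_r = np.nan
        if sub is not None and t_hi >= t_lo:
            ov = sub[(sub["end_bp"] >= t.start_bp) & (sub["start_bp"] <= t.end_bp)]
            if len(ov):
                c_lo = int(np.searchsorted(pos, ov["start_bp"].min(), side="left"))
                c_hi = int(np.searchsorted(pos, ov["end_bp"].max(), side="right")) - 1
                calls = matrix.calls[sample_row[str(t.sample_id)], col_idx]
                hom = (calls == 0) | (calls == 2)
                start_deficit = max(0, c_lo - t_lo)
                end_deficit = max(0, t_hi - c_hi)
                info_start_deficit = int(hom[t_lo : max(t_lo, c_lo)].sum())
                info_end_deficit = int(hom[min(c_hi, t_hi) + 1 : t_hi + 1].sum())
                overrun_l = max(0, t_lo - c_lo)
                overrun_r = max(0, c_hi - t_hi)
                rec = (
                    info_start_deficit <= max_inward_intervals
                    and info_end_deficit <= max_inward_intervals
                )
        rows.append(
            {
                "sample_id": t.sample_id,
                "chrom": t.chrom,
                "start_bp": t.start_bp,
                "end_bp": t.end_bp,
                "length_bp": t.end_bp - t.start_bp + 1,
                "n_markers": max(0, t_hi - t_lo + 1),
                "recovered": rec,
                "start_deficit": start_deficit,
                "end_deficit": end_deficit,
                "info_start_deficit": info_start_deficit,
                "info_end_deficit": info_end_deficit,
                "overrun_left": overrun_l,
                "overrun_right": overrun_r,
            }
        )
    return pd.DataFrame(rows)
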