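"""Synthetic cohorts, cell-line panels and packaged study fixtures.

The generators emit exactly the text formats the readers consume (SEG-style
segments, BED gene annotation, cytoband tables, dose-response TSV) so the
whole pipeline is testable without any download:

* :func:`simulate_cohort` tiles each chromosome of a toy genome with
  segments whose log2 ratios are Gaussian baseline noise, then shifts the
  segments overlapping each planted amplified/deleted region in a
  Bernoulli(population_frequency) subset of samples.
* :func:`simulate_healthy_background` draws independent per-individual
  gain/loss records over genes at given rates (a DGV-like background).
* :func:`simulate_cellline_panel` draws standard-normal gene-level CNV for a
  panel of cell lines and builds 16-point logistic dose-response curves
  whose potency shifts with a planted gene's CNV so that the area under the
  curve is baseline + slope * CNV + Gaussian noise.

All draws come from one ``numpy.random.Generator`` seeded per call; byte
determinism of the emitted files is part of the contract.

The packaged fixtures transcribe the study's in-paper tables (the
recurrent 63-gene panel with per-cohort amplification/deletion frequencies,
the 27 sarcoma cell lines, and the per-profile cohort annotation for the
206 tumor profiles) and are checksum-verified on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genomic_data import CytobandRecord, GeneCNVMatrix, GeneModel, GenomicInterval

MIN_SEGMENT_LEN = 50_000


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture does not match its recorded checksum."""


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------

def default_genome(
    n_chroms: int = 4,
    genes_per_chrom: int = 50,
    bands_per_chrom: int = 3,
    chrom_length: int = 50_000_000,
    gene_length: int = 100_000,
    gene_spacing: int = 950_000,
) -> tuple[list[GeneModel], list[CytobandRecord]]:
    """Deterministic desk-scale genome: 200 genes on 4 chromosomes, 12 bands.

    Gene ``G{c}_{j:02d}`` occupies ``[500_000 + j*spacing,
    500_000 + j*spacing + gene_length)`` on chromosome ``c``; each
    chromosome splits into equal-width bands named p11, q11, q21, ...
    """
    band_names = ["p11", "q11", "q21", "q31", "q41", "q51"]
    genes: list[GeneModel] = []
    bands: list[CytobandRecord] = []
    for c in range(1, n_chroms + 1):
        chrom = str(c)
        for j in range(genes_per_chrom):
            start = 500_000 + j * gene_spacing
            genes.append(GeneModel(f"G{c}_{j:02d}", GenomicInterval(chrom, start, start + gene_length)))
        width = chrom_length // bands_per_chrom
        for b in range(bands_per_chrom):
            lo = b * width
            hi = chrom_length if b == bands_per_chrom - 1 else (b + 1) * width
            bands.append(CytobandRecord(GenomicInterval(chrom, lo, hi), band_names[b]))
    return genes, bands


def genome_to_bed(genes: Sequence[GeneModel]) -> str:
    return "".join(
        f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.symbol}\n"
        for g in genes
    )


def bands_to_cytoband_text(bands: Sequence[CytobandRecord]) -> str:
    return "".join(
        f"{b.interval.chrom}\t{b.interval.start}\t{b.interval.end}\t{b.name}\tgneg\n"
        for b in bands
    )


def _chrom_lengths(genes: Sequence[GeneModel], bands: Sequence[CytobandRecord]) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for g in genes:
        lengths[g.interval.chrom] = max(lengths.get(g.interval.chrom, 0), g.interval.end)
    for b in bands:
        lengths[b.interval.chrom] = max(lengths.get(b.interval.chrom, 0), b.interval.end)
    return lengths


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEvent:
    """A recurrent aberration: region, amp/del, carrier frequency, shift."""

    region: GenomicInterval
    kind: str  # "amp" or "del"
    population_frequency: float
    mean_log2_shift: float

    def __post_init__(self) -> None:
        if self.kind not in ("amp", "del"):
            raise ValueError("kind must be 'amp' or 'del'")
        if not 0.0 <= self.population_frequency <= 1.0:
            raise ValueError("population_frequency must be in [0, 1]")


@dataclass
class CohortSimSpec:
    """Study conditions for one simulated tumor cohort."""

    n_samples: int
    genes: list[GeneModel]
    bands: list[CytobandRecord]
    planted_events: list[PlantedEvent] = field(default_factory=list)
    baseline_sd: float = 0.2
    segment_length_mean: float = 3_000_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be > 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def simulate_cohort(spec: CohortSimSpec) -> str:
    """Generate SEG-style text (0-based half-open dialect) for one cohort.

    Each sample's chromosomes are tiled with segments of exponential length
    (mean ``segment_length_mean``, floor 50 kb) and baseline log2 ratios
    ~ Normal(0, baseline_sd). Every planted event shifts the segments
    overlapping its region by +shift (amp) or -shift (del) in an
    independent Bernoulli(population_frequency) subset of samples.
    """
    lengths = _chrom_lengths(spec.genes, spec.bands)
    for ev in spec.planted_events:
        chrom_len = lengths.get(ev.region.chrom)
        if chrom_len is None or ev.region.end > chrom_len:
            raise ValueError(
                f"planted region {ev.region.chrom}:[{ev.region.start},{ev.region.end}) "
                "lies outside the genome"
            )
    rng = np.random.default_rng(spec.seed)
    carriers = [
        rng.random(spec.n_samples) < ev.population_frequency
        for ev in spec.planted_events
    ]
    chroms = sorted(lengths, key=lambda c: (len(c), c))
    # planted events create breakpoints at their region edges, as real CNV
    # boundaries do; segments never straddle an event edge, so a shift is
    # confined to the planted region
    breakpoints = {
        chrom: sorted({b for ev in spec.planted_events if ev.region.chrom == chrom
                       for b in (ev.region.start, ev.region.end)
                       if 0 < b < lengths[chrom]})
        for chrom in chroms
    }
    lines = ["sample\tchrom\tstart\tend\tseg_mean"]
    for s in range(spec.n_samples):
        sample_id = f"S{s:03d}"
        for chrom in chroms:
            pos = 0
            chrom_len = lengths[chrom]
            while pos < chrom_len:
                seg_len = int(max(MIN_SEGMENT_LEN, rng.exponential(spec.segment_length_mean)))
                raw_end = min(pos + seg_len, chrom_len)
                value = rng.normal(0.0, spec.baseline_sd)
                cuts = [b for b in breakpoints[chrom] if pos < b < raw_end]
                for lo, hi in zip([pos] + cuts, cuts + [raw_end]):
                    piece_value = value
                    for ev, carrier in zip(spec.planted_events, carriers):
                        if carrier[s] and ev.region.chrom == chrom and not (
                            hi <= ev.region.start or lo >= ev.region.end
                        ):
                            piece_value += (ev.mean_log2_shift if ev.kind == "amp"
                                            else -ev.mean_log2_shift)
                    lines.append(
                        f"{sample_id}\t{chrom}\t{lo}\t{hi}\t{float(piece_value)!r}"
                    )
                pos = raw_end
    return "\n".join(lines) + "\n"


# Layout of the default tumor scenario on the default genome (gene indices
# on each chromosome). The amp-filler carrier frequency is chosen so the
# expected amplified share of gene x sample entries stays near 12.5%
# regardless of the target frequency: quantile discretization presupposes a
# genome-wide aberration burden, and holding total burden constant mirrors
# chromosomally unstable tumors whose overall load varies far less than any
# single event's frequency.
_TARGET_GENES = (10, 20)       # chrom 1, genes 10..19 -> 5% of the genome
_FILLER_GENES = (5, 35)        # chroms 2 (amp) and 3 (del), 30 genes each
_TOTAL_AMP_BURDEN = 0.125


def tumor_cohort_spec(
    target_freq: float,
    n_samples: int = 200,
    seed: int = 0,
    baseline_sd: float = 0.2,
    shift: float = 1.0,
) -> tuple[CohortSimSpec, list[str]]:
    """Default tumor-burden scenario on the default genome.

    Plants one target amplification (genes ``G1_10``..``G1_19``) at
    ``target_freq`` plus background amplification/deletion load on
    chromosomes 2 and 3. Returns the spec and the target gene symbols.
    """
    genes, bands = default_genome()
    spacing, length = 950_000, 100_000

    def region(chrom: str, lo: int, hi: int) -> GenomicInterval:
        return GenomicInterval(chrom, 500_000 + lo * spacing,
                               500_000 + (hi - 1) * spacing + length)

    lo, hi = _TARGET_GENES
    target_region = region("1", lo, hi)
    target_symbols = [f"G1_{j:02d}" for j in range(lo, hi)]
    n_genes = len(genes)
    target_mass = (hi - lo) / n_genes * target_freq
    flo, fhi = _FILLER_GENES
    filler_mass_factor = (fhi - flo) / n_genes
    filler_freq = float(np.clip((_TOTAL_AMP_BURDEN - target_mass) / filler_mass_factor, 0.0, 1.0))
    events = [
        PlantedEvent(target_region, "amp", target_freq, shift),
        PlantedEvent(region("2", flo, fhi), "amp", filler_freq, shift),
        PlantedEvent(region("3", flo, fhi), "del", 0.6, shift),
    ]
    spec = CohortSimSpec(
        n_samples=n_samples, genes=genes, bands=bands, planted_events=events,
        baseline_sd=baseline_sd, seed=seed,
    )
    return spec, target_symbols


# ---------------------------------------------------------------------------
# Healthy background simulation
# ---------------------------------------------------------------------------

def simulate_healthy_background(
    n_individuals: int,
    genes: Sequence[GeneModel],
    per_gene_rates,
    seed: int = 0,
):
    """Independent gain/loss records per individual and gene.

    ``per_gene_rates`` is either a ``(gain_rate, loss_rate)`` pair applied
    to every gene or a dict mapping gene symbol to such a pair.
    """
    from .genomic_data import HealthyVariantRecord

    if isinstance(per_gene_rates, dict):
        rates = {g.symbol: per_gene_rates.get(g.symbol, (0.0, 0.0)) for g in genes}
    else:
        rates = {g.symbol: tuple(per_gene_rates) for g in genes}
    for gain, loss in rates.values():
        if not (0.0 <= gain <= 1.0 and 0.0 <= loss <= 1.0):
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_individuals):
        ind = f"H{i:04d}"
        for g in genes:
            gain, loss = rates[g.symbol]
            if rng.random() < gain:
                records.append(HealthyVariantRecord(ind, g.interval, "gain"))
            if rng.random() < loss:
                records.append(HealthyVariantRecord(ind, g.interval, "loss"))
    return records


# ---------------------------------------------------------------------------
# Cell-line panel with dose-response curves
# ---------------------------------------------------------------------------

@dataclass
class PanelSimSpec:
    """Study conditions for a simulated cell-line CNV + drug screen."""

    n_cell_lines: int = 27
    drugs: list[str] = field(default_factory=lambda: ["drug_A"])
    doses_per_drug: int = 16
    planted_links: list[tuple[str, str, float]] = field(default_factory=list)
    auc_noise_sd: float = 0.1
    baseline_auc: Optional[float] = None
    min_concentration: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.doses_per_drug < 4:
            raise ValueError("doses_per_drug must be >= 4")
        seen = set()
        for gene, drug, _ in self.planted_links:
            if (gene, drug) in seen:
                raise ValueError(f"duplicate planted link for ({gene}, {drug})")
            seen.add((gene, drug))


def _logistic(x: np.ndarray, x0: float) -> np.ndarray:
    # viability 0.5 at x0, one log2 unit of steepness
    return 1.0 / (1.0 + np.exp2(x - x0))


def _solve_potency(x: np.ndarray, target_auc: float) -> float:
    """x0 such that the trapezoidal AUC of the logistic over ``x`` hits target."""
    lo, hi = x[0] - 60.0, x[-1] + 60.0

    def f(x0: float) -> float:
        return float(np.trapezoid(_logistic(x, x0), x)) - target_auc

    return float(brentq(f, lo, hi, xtol=1e-13, maxiter=200))


def simulate_cellline_panel(
    spec: PanelSimSpec, genes: Sequence[GeneModel]
) -> tuple[GeneCNVMatrix, str]:
    """Cell-line CNV matrix plus a dose-response TSV.

    Gene-level CNV values are standard normal per gene and line. Each drug's
    viability curve for a line is a logistic in log2 concentration whose
    potency is solved so that the trapezoidal AUC equals
    ``baseline + slope * CNV + Normal(0, auc_noise_sd)`` for planted
    (gene, drug) links, and ``baseline + noise`` otherwise. Targets are
    clipped into the achievable (1%..99% of span) AUC range.
    """
    rng = np.random.default_rng(spec.seed)
    lines = [f"CL{i:02d}" for i in range(spec.n_cell_lines)]
    values = rng.normal(0.0, 1.0, size=(len(genes), spec.n_cell_lines))
    df = pd.DataFrame(values, index=[g.symbol for g in genes], columns=lines)
    matrix = GeneCNVMatrix(genes=list(genes), values=df, cohort_label="CELLLINE")

    conc = spec.min_concentration * np.exp2(np.arange(spec.doses_per_drug))
    x = np.log2(conc)
    span = float(x[-1] - x[0])
    baseline = 0.55 * span if spec.baseline_auc is None else spec.baseline_auc
    links = {(g, d): s for g, d, s in spec.planted_links}
    for gene, drug in links:
        if gene not in df.index:
            raise ValueError(f"planted link gene {gene!r} not in the gene list")
        if drug not in spec.drugs:
            raise ValueError(f"planted link drug {drug!r} not in the drug list")

    rows = ["cell_line\tdrug\tconcentration\tviability"]
    for drug in spec.drugs:
        slopes = {g: s for (g, d), s in links.items() if d == drug}
        for j, line in enumerate(lines):
            target = baseline + sum(s * df.at[g, line] for g, s in slopes.items())
            target += rng.normal(0.0, spec.auc_noise_sd)
            target = float(np.clip(target, 0.01 * span, 0.99 * span))
            x0 = _solve_potency(x, target)
            viab = _logistic(x, x0)
            for c, v in zip(conc, viab):
                rows.append(f"{line}\t{drug}\t{float(c)!r}\t{float(v)!r}")
    return matrix, "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_bytes(name: str) -> bytes:
    ref = resources.files("sarcnv.fixtures").joinpath(name)
    data = ref.read_bytes()
    checksums = json.loads(
        resources.files("sarcnv.fixtures").joinpath("checksums.json").read_text()
    )
    expected = checksums.get(name)
    digest = hashlib.sha256(data).hexdigest()
    if expected is None or digest != expected:
        raise FixtureIntegrityError(
            f"fixture {name} failed checksum verification ({digest} != {expected})"
        )
    return data


def _fixture_frame(name: str, **kwargs) -> pd.DataFrame:
    from io import BytesIO

    return pd.read_csv(BytesIO(_fixture_bytes(name)), sep="\t", **kwargs)


def load_gene_panel_fixture() -> pd.DataFrame:
    """The recurrent 63-gene panel with per-cohort amp/del frequencies.

    Columns: no, band, gene, os_amp, os_del, rms_amp, rms_del, esft_amp,
    esft_del, n_sarcoma_flags, flag_os, flag_rms, flag_esft, druggable.
    Frequencies are fractions over the 206 tumor profiles; blank cells in
    the source table are missing values.
    """
    return _fixture_frame("gene_panel.tsv", dtype={"band": str, "gene": str})


def load_cellline_fixture() -> pd.DataFrame:
    """The 27 profiled sarcoma cell lines (tissue, histology, cell_line)."""
    return _fixture_frame("cell_lines.tsv")


def load_cohort_annotation_fixture() -> pd.DataFrame:
    """Per-profile cohort annotation: profile_id, cohort, source, platform.

    One row per tumor profile (117 OS, 64 RMS, 25 ESFT; 206 in total).
    """
    return _fixture_frame("cohorts.tsv")
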