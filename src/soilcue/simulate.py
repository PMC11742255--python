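"""Synthetic-study generator with known ground truth.

Emulates the field design — 15 tree species (8 arbuscular-mycorrhizal, 7
ectomycorrhizal) × 2 sampling positions (rhizosphere, non-rhizosphere) × 5
replicate trees = 150 samples — by *inverting* the downstream analysis:
group-level true rates and pool sizes are converted back into the raw
measurements (O content and at% ¹⁸O of DNA extracts, headspace CO₂,
fumigation extract concentrations, OTU counts), so that at zero noise the
analysis modules recover the truth exactly, and every stage has a recovery
test with a known answer.

Measurement noise is multiplicative log-normal (all measured quantities are
positive), applied to the informative part of each reading: the at% ¹⁸O
excess, the O content of the extract, the produced CO₂, and the extract
concentrations. OTU counts are drawn per sample as multinomial reads over
multivariate log-normal basis abundances with a known basis correlation
matrix — the generative model under which SparCC is consistent — providing
ground truth for network-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemistry, isotope
from ._util import derive_seed
from .community import OtuTable
from .isotope import IncubationConfig, NATURAL_ABUNDANCE_ATPCT

POSITIONS = ("non_rhizosphere", "rhizosphere")


@dataclass(frozen=True)
class GroupEffects:
    """True group-level means for one (mycorrhizal type, position) cell.

    Rates in ng C g⁻¹ h⁻¹; pools in μg g⁻¹ dry soil.
    """

    mean_growth: float
    mean_respiration: float
    mean_mbc: float
    mean_mbn: float
    mean_doc: float
    mean_tdn: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"GroupEffects.{name} must be > 0")


@dataclass
class StudyDesign:
    """Factorial layout and true effects of a synthetic study."""

    species_list: list[tuple[str, str]]  # (species_name, 'AM'|'ECM')
    replicates_per_cell: int
    group_effects: dict[tuple[str, str], GroupEffects]  # (myc, position) -> effects
    noise_cv: float = 0.15
    pH: float = 5.8

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        myc_types = {m for _, m in self.species_list}
        for m in myc_types:
            for p in POSITIONS:
                if (m, p) not in self.group_effects:
                    raise ValueError(f"group_effects missing cell {(m, p)}")

    @property
    def n_samples(self) -> int:
        return len(self.species_list) * len(POSITIONS) * self.replicates_per_cell


def default_design(noise_cv: float = 0.15) -> StudyDesign:
    """The study-scale default: 8 AM + 7 ECM species, 2 positions, 5 replicates.

    True effects plant the headline contrasts: a 0.2 absolute CUE difference
    between ECM (0.45) and AM (0.25) non-rhizosphere soils, driven by growth;
    higher respiration (hence lower CUE) in ECM rhizosphere than ECM
    non-rhizosphere; higher MBC, MBN and DOC/TDN under ECM. Magnitudes sit
    inside the field-observed growth range of roughly 16–390 ng C g⁻¹ h⁻¹.
    """
    species = [(f"AM_sp{i:02d}", "AM") for i in range(1, 9)] + [
        (f"ECM_sp{i:02d}", "ECM") for i in range(1, 8)
    ]
    effects = {
        ("AM", "non_rhizosphere"): GroupEffects(80.0, 240.0, 300.0, 40.0, 60.0, 8.0),
        ("AM", "rhizosphere"): GroupEffects(90.0, 270.0, 320.0, 42.0, 65.0, 8.5),
        ("ECM", "non_rhizosphere"): GroupEffects(150.0, 550.0 / 3.0, 450.0, 60.0, 90.0, 7.0),
        ("ECM", "rhizosphere"): GroupEffects(150.0, 350.0, 430.0, 58.0, 95.0, 7.5),
    }
    return StudyDesign(species, 5, effects, noise_cv=noise_cv)


@dataclass
class BasisCorrelationSpec:
    """Ground-truth generative model for one domain's OTU counts."""

    n_taxa: int
    correlation_matrix: np.ndarray
    log_mean_abundances: np.ndarray
    log_sd: np.ndarray
    sequencing_depth: int

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        c = np.asarray(self.correlation_matrix, dtype=float)
        if c.shape != (self.n_taxa, self.n_taxa):
            raise ValueError("correlation_matrix shape mismatch")
        if not np.allclose(c, c.T):
            raise ValueError("correlation_matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation_matrix must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ValueError("correlation_matrix must be positive semidefinite")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be > 0")


def planted_pairs_correlation(n_taxa: int, pairs: list[tuple[int, int, float]]) -> np.ndarray:
    """Identity correlation matrix with disjoint planted pairs (always PSD)."""
    c = np.eye(n_taxa)
    used: set[int] = set()
    for i, j, rho in pairs:
        if i in used or j in used:
            raise ValueError("planted pairs must be disjoint")
        used.update((i, j))
        c[i, j] = c[j, i] = rho
    return c


def default_basis_spec(domain: str) -> BasisCorrelationSpec:
    """Study-scale generative defaults per domain.

    Bacteria: 60 taxa at depth 25 000 reads (rarefied downstream to 20 981);
    fungi: 30 taxa at depth 10 000 (rarefied to 8542). Each domain carries
    three planted blocks of strongly co-varying taxa (basis ρ = 0.85) among
    the abundant, prevalent taxa — the signal the co-occurrence networks
    should pick up — plus a low-abundance tail that the prevalence filters
    (80% bacteria / 50% fungi) are expected to remove.
    """
    rng = np.random.default_rng(derive_seed(20260101, f"basis-spec-{domain}"))
    if domain == "bacteria":
        n_taxa, depth, n_blocks = 60, 25000, 3
    elif domain == "fungi":
        n_taxa, depth, n_blocks = 30, 10000, 3
    else:
        raise ValueError(f"unknown domain {domain!r}")
    corr = np.eye(n_taxa)
    block = 4
    for b in range(n_blocks):
        idx = np.arange(b * block, (b + 1) * block)
        corr[np.ix_(idx, idx)] = 0.85
    np.fill_diagonal(corr, 1.0)
    # abundant head (prevalent everywhere), rare tail removed by prevalence filter
    n_rare = n_taxa // 5
    log_means = np.concatenate(
        [
            rng.normal(4.0, 0.8, n_taxa - n_rare),
            rng.normal(-2.5, 0.5, n_rare),
        ]
    )
    log_sd = np.full(n_taxa, 1.0)
    return BasisCorrelationSpec(n_taxa, corr, log_means, log_sd, depth)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def simulate_incubation(
    truth: pd.DataFrame,
    config: IncubationConfig = isotope.DEFAULT_CONFIG,
    noise_cv: float = 0.0,
    seed: int = 0,
    DW: float = 1.0,
    t: float = 24.0,
    dna_content: float = 15.0,
    O_total: float = 25.0,
    atpct_final: float = 20.0,
    blank_ppm_mean: float = 10.0,
) -> pd.DataFrame:
    """Invert the rate equations into raw incubation measurements.

    ``truth`` needs columns sample_id, growth, respiration and MBC (the true
    biomass C governing f_DNA; μg g⁻¹); an optional ``MBC_measured`` column
    is what the record carries for the analyst's conversion (defaults to the
    true MBC). The labelled vial's at% ¹⁸O is the natural-abundance control
    value plus the excess implied by the true growth rate; headspace CO₂ is
    the blank mean plus the mixing ratio implied by the true respiration
    rate. Multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` is applied independently to the O content, the at% excess
    and the produced CO₂ — noise on O and at% therefore propagates into
    recomputed growth as a product, as in the real assay. At ``noise_cv=0``
    the records reproduce the truth exactly through
    :func:`soilcue.isotope.process_incubation_table`.
    """
    if (truth[["growth", "respiration", "MBC"]] <= 0).any().any():
        raise ValueError("true growth, respiration and MBC must be > 0")
    rng = np.random.default_rng(seed)
    n = len(truth)
    c = config

    f_dna = truth["MBC"].to_numpy() / dna_content
    dna_prod = truth["growth"].to_numpy() * DW * t / (f_dna * 1000.0)
    o_total = O_total * _lognormal_noise(rng, noise_cv, n)
    excess = (
        dna_prod * atpct_final * c.o_pct_in_dna / (O_total * 100.0)
    ) * _lognormal_noise(rng, noise_cv, n)
    atpct_labeled = NATURAL_ABUNDANCE_ATPCT + excess
    if (atpct_labeled >= 100).any() or (atpct_labeled >= atpct_final).any():
        raise ValueError("implied at% exceeds the labelling level; reduce true growth")

    rs = (
        truth["respiration"].to_numpy()
        * DW
        * t
        * (c.gas_constant * c.temperature_k)
        / (c.pressure_kpa * c.molar_mass_c * c.headspace_volume_l * 1000.0)
    )
    co2 = rs * _lognormal_noise(rng, noise_cv, n) + blank_ppm_mean

    return pd.DataFrame(
        {
            "sample_id": truth["sample_id"].to_numpy(),
            "O_total": o_total,
            "atpct_labeled": atpct_labeled,
            "atpct_control": NATURAL_ABUNDANCE_ATPCT,
            "atpct_final": atpct_final,
            "co2_ppm": co2,
            "blank_ppm_mean": blank_ppm_mean,
            "DW": DW,
            "t": t,
            "dna_content": dna_content,
            "MBC": (
                truth["MBC_measured"] if "MBC_measured" in truth else truth["MBC"]
            ).to_numpy(),
        }
    )


def simulate_fumigation(
    truth: pd.DataFrame, noise_cv: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Invert the fumigation-extraction conversion into extract pairs.

    ``truth`` needs columns sample_id, MBC, MBN, DOC, TDN (all > 0, μg g⁻¹).
    Before noise, fumigated DOC = DOC + 0.45·MBC and fumigated TDN =
    TDN + 0.54·MBN; each of the four extract concentrations then receives
    independent multiplicative log-normal noise.
    """
    if (truth[["MBC", "MBN", "DOC", "TDN"]] <= 0).any().any():
        raise ValueError("true MBC, MBN, DOC and TDN must be > 0")
    rng = np.random.default_rng(seed)
    n = len(truth)
    doc = truth["DOC"].to_numpy()
    tdn = truth["TDN"].to_numpy()
    return pd.DataFrame(
        {
            "sample_id": truth["sample_id"].to_numpy(),
            "doc_fumigated": (doc + chemistry.MBC_CONVERSION * truth["MBC"].to_numpy())
            * _lognormal_noise(rng, noise_cv, n),
            "doc_unfumigated": doc * _lognormal_noise(rng, noise_cv, n),
            "tdn_fumigated": (tdn + chemistry.MBN_CONVERSION * truth["MBN"].to_numpy())
            * _lognormal_noise(rng, noise_cv, n),
            "tdn_unfumigated": tdn * _lognormal_noise(rng, noise_cv, n),
        }
    )


def simulate_otu_table(
    spec: BasisCorrelationSpec,
    n_samples: int,
    seed: int = 0,
    domain: str = "bacteria",
    sample_ids: list[str] | None = None,
) -> OtuTable:
    """Multinomial reads over multivariate log-normal basis abundances.

    Per sample, log basis abundances are drawn multivariate normal with the
    spec's correlation structure, exponentiated, closed to fractions, and
    ``sequencing_depth`` reads are drawn multinomial — so every sample column
    sums to exactly the stated depth.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    sd = np.asarray(spec.log_sd, dtype=float)
    cov = spec.correlation_matrix * np.outer(sd, sd)
    # eigendecomposition root: tolerant of the semidefinite boundary
    vals, vecs = np.linalg.eigh(cov)
    root = vecs @ np.diag(np.sqrt(np.maximum(vals, 0.0)))
    z = rng.standard_normal((n_samples, spec.n_taxa))
    basis = np.exp(np.asarray(spec.log_mean_abundances) + z @ root.T)
    fractions = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng.multinomial(spec.sequencing_depth, f) for f in fractions]
    ).T  # taxa × samples
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    taxon_ids = [f"{'B' if domain == 'bacteria' else 'F'}_OTU{i:04d}" for i in range(spec.n_taxa)]
    return OtuTable(pd.DataFrame(counts, index=taxon_ids, columns=sample_ids), domain)


@dataclass
class SyntheticStudy:
    """All tables of one synthetic study plus the ground-truth sidecar."""

    metadata: pd.DataFrame
    incubation: pd.DataFrame
    fumigation: pd.DataFrame
    bacteria: OtuTable
    fungi: OtuTable
    truth: pd.DataFrame
    seed: int

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit every table the pipeline consumes, plus the truth sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "metadata": out / "metadata.tsv",
            "incubation": out / "incubation.tsv",
            "fumigation": out / "fumigation.tsv",
            "otu_bacteria": out / "otu_bacteria.tsv",
            "otu_fungi": out / "otu_fungi.tsv",
            "truth": out / "truth.tsv",
        }
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        self.incubation.to_csv(paths["incubation"], sep="\t", index=False)
        self.fumigation.to_csv(paths["fumigation"], sep="\t", index=False)
        self.bacteria.to_tsv(paths["otu_bacteria"])
        self.fungi.to_tsv(paths["otu_fungi"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate_study(
    design: StudyDesign | None = None,
    bacterial_spec: BasisCorrelationSpec | None = None,
    fungal_spec: BasisCorrelationSpec | None = None,
    seed: int = 0,
    config: IncubationConfig = isotope.DEFAULT_CONFIG,
) -> SyntheticStudy:
    """Generate a complete synthetic study from a design and basis specs.

    Per-sample truth is the group mean of the sample's (mycorrhizal type,
    position) cell; all sampling variation enters through the measurement
    noise model. The fumigation extracts are simulated first and the
    *measured* MBC they imply is carried into the incubation records, exactly
    as the real workflow feeds fumigation-derived MBC into f_DNA.
    """
    design = design or default_design()
    bacterial_spec = bacterial_spec or default_basis_spec("bacteria")
    fungal_spec = fungal_spec or default_basis_spec("fungi")

    rows = []
    for species, myc in design.species_list:
        for position in POSITIONS:
            eff = design.group_effects[(myc, position)]
            for rep in range(1, design.replicates_per_cell + 1):
                rows.append(
                    {
                        "sample_id": f"{species}_{'R' if position == 'rhizosphere' else 'N'}_{rep}",
                        "species": species,
                        "mycorrhizal_type": myc,
                        "position": position,
                        "replicate": rep,
                        "growth": eff.mean_growth,
                        "respiration": eff.mean_respiration,
                        "MBC": eff.mean_mbc,
                        "MBN": eff.mean_mbn,
                        "DOC": eff.mean_doc,
                        "TDN": eff.mean_tdn,
                    }
                )
    truth = pd.DataFrame(rows)
    truth["uptake"] = truth["growth"] + truth["respiration"]
    truth["cue"] = truth["growth"] / truth["uptake"]
    truth["imbalance"] = (truth["DOC"] / truth["TDN"]) / (truth["MBC"] / truth["MBN"])
    truth["pH"] = design.pH

    fumigation = simulate_fumigation(
        truth, design.noise_cv, derive_seed(seed, "fumigation")
    )
    # true MBC governs the physics; the fumigation-measured MBC is what the
    # record carries into the analyst's f_DNA conversion, as in the real workflow
    measured = chemistry.process_chemistry_table(fumigation).set_index("sample_id")
    incub_truth = truth[["sample_id", "growth", "respiration", "MBC"]].copy()
    incub_truth["MBC_measured"] = measured.loc[truth["sample_id"], "MBC"].to_numpy()
    incubation = simulate_incubation(
        incub_truth, config, design.noise_cv, derive_seed(seed, "incubation")
    )

    sample_ids = list(truth["sample_id"])
    bacteria = simulate_otu_table(
        bacterial_spec,
        len(sample_ids),
        derive_seed(seed, "otu-bacteria"),
        "bacteria",
        sample_ids,
    )
    fungi = simulate_otu_table(
        fungal_spec, len(sample_ids), derive_seed(seed, "otu-fungi"), "fungi", sample_ids
    )

    metadata = truth[
        ["sample_id", "species", "mycorrhizal_type", "position", "replicate", "pH"]
    ].copy()
    return SyntheticStudy(metadata, incubation, fumigation, bacteria, fungi, truth, seed)
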