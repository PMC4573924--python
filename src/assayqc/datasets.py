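"""Published characterization data for the validated 50-gene hotspot assay.

These tables are the printed inputs of the validation study this package
operationalizes: per-cell-line variant allele frequencies for the four
characterized cancer lines (fresh-frozen and FFPE preparations) and the
normal placental diluent, the run/call metric summaries the acceptance
cutoffs were derived from, the 55-sample clinical cohort scored against
single-gene assays, the recurrent-variant blacklist, and the QC material's
baseline statistics.

Positions are hg19, 1-based, as printed.  The source tables print only the
*alternate* base for most loci, so reference bases here are synthetic
placeholders (a base differing from the alt) except where the recurrent-
variant list states the actual change; indel alleles likewise carry
synthetic VCF-style anchor bases.  Frequencies, positions, genes and alt
alleles are the published values.
"""

from __future__ import annotations

from .concordance import ReferenceResult
from .lod import DetectionSeries
from .mixtures import CopyState, ExpectedProfile, LineProfile, LocusGenotype
from .run_qc import RoundingPolicy
from .variants_io import VariantKey

GENE_CHROM = {
    "ABL1": "chr9", "APC": "chr5", "ATM": "chr11", "BRAF": "chr7",
    "CDKN2A": "chr9", "CSF1R": "chr5", "CTNNB1": "chr3", "EGFR": "chr7",
    "ERBB4": "chr2", "FGFR3": "chr4", "FLT3": "chr13", "HRAS": "chr11",
    "KDR": "chr4", "KRAS": "chr12", "MET": "chr7", "NOTCH1": "chr9",
    "PDGFRA": "chr4", "PIK3CA": "chr3", "PTEN": "chr10", "RB1": "chr13",
    "RET": "chr10", "SMAD4": "chr18", "SMARCB1": "chr22", "SMO": "chr7",
    "STK11": "chr19", "TP53": "chr17",
}

# actual reference bases, where the published recurrent-variant list
# states the change explicitly
_KNOWN_REF = {
    ("EGFR", 55249063): "G", ("FGFR3", 1807894): "G",
    ("FLT3", 28610183): "T", ("PDGFRA", 55141055): "A",
    ("CSF1R", 149433596): "A", ("CSF1R", 149433597): "C",
    ("STK11", 1220321): "T",
}


def _key(gene: str, pos: int, alt: str) -> VariantKey:
    """Variant key with a placeholder ref base where unpublished."""
    if alt.startswith("DEL"):  # display form "DELxxx": deletion of the bases
        deleted = alt[3:]
        anchor = "A" if deleted[0] != "A" else "C"
        return VariantKey(GENE_CHROM[gene], pos, anchor + deleted, anchor, gene)
    ref = _KNOWN_REF.get((gene, pos)) or ("A" if alt != "A" else "C")
    return VariantKey(GENE_CHROM[gene], pos, ref, alt, gene)


# ---------------------------------------------------------------------------
# fresh-frozen cell line characterization (dilution into placental DNA)
# columns: gene, pos, alt, HCT116, MiaPaCa-2, H1975, SK-MEL-28, Placenta,
#          printed expected: equal mix, dilution 1:2, dilution 1:3
# None = variant not applicable (0% / absent)
# ---------------------------------------------------------------------------

_FROZEN = [
    ("ABL1", 133738370, "G", 52.4, None, None, None, None, 13.1, 6.1, 4.1),
    ("APC", 112175770, "A", 98.1, 74.4, 51.7, 88.5, 2.1, 78.1, 40.7, 27.8),
    ("ATM", 108138003, "C", None, None, None, None, 55.8, None, 27.9, 37.2),
    ("BRAF", 140453136, "A", None, None, None, 99.3, None, 24.8, 12.3, 8.2),
    ("CDKN2A", 21971153, "T", None, None, 96.4, None, None, 24.1, 16.9, 11.3),
    ("CSF1R", 149433596, "C", 99.6, 99.3, 100.0, None, 90.5, 74.7, 72.9, 78.8),
    ("CSF1R", 149433597, "T", 99.6, 99.1, 100.0, None, 93.2, 74.7, 74.3, 80.6),
    ("CTNNB1", 41266134, "DELCTT", 50.2, None, None, None, None, 12.5, 4.7, 3.2),
    ("EGFR", 55242487, "T", None, None, None, 99.3, None, 24.8, 12.3, 8.2),
    ("EGFR", 55249063, "A", 100.0, 23.2, 70.6, 100.0, 97.6, 73.4, 85.9, 89.8),
    ("EGFR", 55249071, "T", None, None, 70.7, None, None, 17.7, 12.7, 8.4),
    ("EGFR", 55259515, "G", None, None, 56.7, None, None, 14.2, 9.2, 6.1),
    ("ERBB4", 212812097, "G", 100.0, None, 75.9, None, 62.9, 44.0, 58.4, 59.9),
    ("FGFR3", 1807894, "A", 100.0, 100.0, 99.6, 100.0, 100.0, 99.9, 99.9, 99.9),
    ("FLT3", 28602367, "A", 46.9, None, None, None, None, 11.7, 8.8, 5.9),
    ("FLT3", 28610183, "C", 100.0, 66.5, 99.6, 69.2, 100.0, 83.8, 90.9, 93.9),
    ("HRAS", 534242, "C", 99.5, 61.9, 40.4, 46.9, 2.6, 62.2, 34.7, 24.0),
    ("KDR", 55946354, "A", 48.5, None, None, None, 51.3, 12.1, 33.3, 39.3),
    ("KDR", 55972974, "T", 52.6, None, None, None, None, 13.1, 8.1, 5.4),
    ("KRAS", 25398281, "A", 46.4, None, None, None, None, 11.6, 5.9, 3.9),
    ("KRAS", 25398285, "T", None, 99.9, None, None, None, 25.0, 12.8, 8.5),
    ("MET", 116339672, "T", None, 72.9, None, None, None, 18.2, 6.9, 4.6),
    ("NOTCH1", 139390822, "G", None, 100.0, None, None, None, 25.0, 11.1, 7.4),
    ("PDGFRA", 55141055, "G", 99.7, 100.0, 99.7, 100.0, 99.9, 99.8, 99.8, 99.8),
    ("PDGFRA", 55152040, "T", None, None, 50.8, None, 3.8, 12.7, 8.8, 7.1),
    ("PIK3CA", 178917005, "G", None, None, 100.0, None, None, 25.0, 11.6, 7.8),
    ("PIK3CA", 178927410, "G", None, None, 45.1, None, None, 11.3, 5.8, 3.9),
    ("PIK3CA", 178952085, "G", 47.7, None, None, None, None, 11.9, 4.9, 3.2),
    ("PTEN", 89711881, "G", None, None, None, 99.3, None, 24.8, 11.8, 7.9),
    ("RET", 43613843, "T", 100.0, 65.8, 100.0, None, 100.0, 66.4, 86.1, 90.7),
    ("RET", 43615612, "G", 45.2, None, None, None, None, 11.3, 7.4, 5.0),
    ("RET", 43615633, "G", None, 64.5, None, None, None, 16.1, 7.1, 4.7),
    ("SMAD4", 48586344, "T", 47.6, None, None, None, None, 11.9, 8.1, 5.4),
    ("SMARCB1", 24176287, "A", 50.7, None, 40.8, None, None, 22.9, 11.8, 7.9),
    ("SMO", 128846374, "A", 52.6, None, None, None, None, 13.1, 5.8, 3.9),
    ("TP53", 7577025, "T", None, None, None, None, 79.0, None, 39.5, 52.6),
    ("TP53", 7577120, "A", None, None, 99.9, None, None, 25.0, 16.7, 11.1),
    ("TP53", 7577539, "T", None, 99.5, None, None, None, 24.9, 9.6, 6.4),
    ("TP53", 7579472, "G", 94.2, None, 94.2, None, 20.4, 47.1, 45.1, 36.9),
]

FROZEN_LINE_NAMES = ("HCT116", "MiaPaCa-2", "H1975", "SK-MEL-28")
PLACENTA = "Placenta"

# ---------------------------------------------------------------------------
# FFPE cell line characterization
# columns: gene, pos, alt, HCT116, MiaPaCa-2, H1975, SK-MEL-28,
#          printed expected: equal mix, H1975-in-MiaPaCa-2 dilution
# ---------------------------------------------------------------------------

_FFPE = [
    ("ABL1", 133738370, "G", 37.0, None, None, None, 9.3, 0.0),
    ("APC", 112175770, "A", 98.0, 72.7, 36.5, 91.3, 74.6, 70.2),
    ("BRAF", 140453136, "A", None, None, None, 100.0, 25.0, 0.0),
    ("CDKN2A", 21971153, "T", None, None, 98.8, None, 24.7, 100.0),
    ("CSF1R", 149433596, "C", 100.0, 100.0, 100.0, None, 75.0, 100.0),
    ("CSF1R", 149433597, "T", 95.7, 96.1, 97.2, None, 72.3, 96.2),
    ("CTNNB1", 41266134, "DELCTT", 44.9, None, None, None, 11.2, 0.0),
    ("EGFR", 55242487, "T", None, None, None, 100.0, 25.0, 0.0),
    ("EGFR", 55249063, "A", 100.0, 35.6, 75.3, 100.0, 77.7, 38.4),
    ("EGFR", 55249071, "T", None, None, 74.8, None, 18.7, 5.2),
    ("EGFR", 55259515, "G", None, None, 71.7, None, 17.9, 5.0),
    ("ERBB4", 212812097, "G", 100.0, None, 72.3, None, 43.1, 5.1),
    ("FGFR3", 1807894, "A", 100.0, 100.0, 100.0, 100.0, 100.0, 100.0),
    ("FLT3", 28602367, "A", 49.5, None, None, None, 12.4, 0.0),
    ("FLT3", 28610183, "C", 100.0, 64.3, 100.0, 65.2, 82.4, 66.8),
    ("HRAS", 534242, "C", 98.9, 47.8, 38.9, 48.5, 58.5, 47.2),
    ("KDR", 55946354, "A", 47.9, None, None, None, 12.0, 0.0),
    ("KDR", 55972974, "T", 47.1, None, None, None, 11.8, 0.0),
    ("KRAS", 25398281, "A", 47.7, None, None, None, 11.9, 0.0),
    ("KRAS", 25398285, "T", None, 100.0, None, None, 25.0, 93.0),
    ("MET", 116339672, "T", None, 70.3, None, None, 17.6, 65.4),
    ("NOTCH1", 139390822, "G", None, 100.0, None, None, 25.0, 93.0),
    ("PDGFRA", 55141055, "G", 100.0, 100.0, 100.0, 100.0, 100.0, 100.0),
    ("PDGFRA", 55152040, "T", None, None, 51.3, None, 12.8, 3.6),
    ("PIK3CA", 178917005, "G", None, None, 100.0, None, 25.0, 7.0),
    ("PIK3CA", 178927410, "G", None, None, 47.1, None, 11.8, 3.3),
    ("PIK3CA", 178952085, "G", 47.7, None, None, None, 11.9, 0.0),
    ("PTEN", 89711881, "G", None, None, None, 100.0, 25.0, 0.0),
    ("RET", 43613843, "T", 100.0, 67.5, 100.0, None, 66.9, 69.8),
    ("RET", 43615612, "G", 49.1, None, None, None, 12.3, 0.0),
    ("RET", 43615633, "G", None, 65.1, None, None, 16.3, 60.5),
    ("SMAD4", 48586344, "T", 50.6, None, None, None, 12.7, 0.0),
    ("SMARCB1", 24176287, "A", 52.1, None, 46.3, None, 24.6, 3.2),
    ("SMO", 128846374, "A", 51.0, None, None, None, 12.8, 0.0),
    ("TP53", 7577120, "A", None, None, 100.0, None, 25.0, 7.0),
    ("TP53", 7577539, "T", None, 99.9, None, None, 25.0, 92.9),
    ("TP53", 7579472, "G", 84.2, None, 90.8, None, 43.8, 6.4),
]


def _profiles(rows, line_names, freq_columns) -> dict[str, LineProfile]:
    profiles = {name: {} for name in line_names}
    for row in rows:
        gene, pos, alt = row[0], row[1], row[2]
        key = _key(gene, pos, alt)
        for name, col in zip(line_names, freq_columns):
            freq = row[col]
            if freq is not None:
                profiles[name][key] = LocusGenotype(freq, CopyState.NORMAL)
    return {name: LineProfile(name, entries) for name, entries in profiles.items()}


def frozen_line_profiles() -> dict[str, LineProfile]:
    """Measured per-line VAFs of the fresh-frozen preparations, plus the
    normal placental diluent's germline variants."""
    return _profiles(_FROZEN, FROZEN_LINE_NAMES + (PLACENTA,), (3, 4, 5, 6, 7))


def ffpe_line_profiles() -> dict[str, LineProfile]:
    """Measured per-line VAFs of the FFPE preparations."""
    return _profiles(_FFPE, FROZEN_LINE_NAMES, (3, 4, 5, 6))


def _printed(rows, col) -> dict[VariantKey, float]:
    return {
        _key(r[0], r[1], r[2]): r[col]
        for r in rows if r[col] is not None
    }


def frozen_expected_printed() -> dict[str, dict[VariantKey, float]]:
    """Printed expected VAFs for the frozen experiments, per column."""
    return {
        "equal_mix": _printed(_FROZEN, 8),
        "dilution_1_2": _printed(_FROZEN, 9),
        "dilution_1_3": _printed(_FROZEN, 10),
    }


def ffpe_expected_printed() -> dict[str, dict[VariantKey, float]]:
    return {
        "equal_mix": _printed(_FFPE, 7),
        "h1975_in_miapaca": _printed(_FFPE, 8),
    }


def ffpe_dilution_profiles() -> tuple[LineProfile, LineProfile]:
    """Genotype profiles for the H1975-in-MiaPaCa-2 dilution expectation.

    Expected columns for dilutions were computed from idealized genotypes:
    H1975's CDKN2A variant is homozygous (100%) and MiaPaCa-2 carries a
    homozygous deletion of CDKN2A, so the locus stays at 100% expected at
    any mixing ratio (only H1975 contributes templates there).
    """
    profiles = ffpe_line_profiles()
    cdkn2a = _key("CDKN2A", 21971153, "T")
    h1975 = profiles["H1975"]
    h1975.entries[cdkn2a] = LocusGenotype(100.0, CopyState.NORMAL)
    miapaca = profiles["MiaPaCa-2"]
    miapaca.entries[cdkn2a] = LocusGenotype(0.0, CopyState.HOM_DELETION)
    return h1975, miapaca


# ---------------------------------------------------------------------------
# run-metric summaries behind the published acceptance cutoffs
# ---------------------------------------------------------------------------

def metric_summaries() -> list[dict]:
    """Published mean/SD summaries and the z/rounding convention that
    reproduces each printed cutoff.

    The quality metric was normal only after a log10 transform, so its
    summary lives on that scale and the bound is back-transformed
    (anti-log) before rounding.
    """
    return [
        dict(metric_name="coverage", mean=1231.0, sd=526.0,
             confidence_pct=95.0, z=1.96, side="lower",
             transform="identity", rounding=RoundingPolicy("integer")),
        dict(metric_name="q20_bases", mean=2.5e7, sd=2.4e6,
             confidence_pct=95.0, z=1.96, side="lower",
             transform="identity", rounding=RoundingPolicy("sigfigs", 2)),
        dict(metric_name="quality", mean=3.65, sd=0.45,
             confidence_pct=99.0, z=2.576, side="lower",
             transform="log10", rounding=RoundingPolicy("sigfigs", 1)),
        dict(metric_name="strand_bias", mean=0.7, sd=0.04,
             confidence_pct=99.0, z=2.326, side="upper",
             transform="identity", rounding=RoundingPolicy("decimals", 2)),
    ]


# ---------------------------------------------------------------------------
# clinical validation cohort (55 samples, three queried genes)
# ---------------------------------------------------------------------------

CONCORDANCE_GENES = ("KRAS", "EGFR", "BRAF")

# sample suffix, gene or None (negative), reference hgvs, test hgvs or
# None when the panel called nothing reportable in the queried genes
_COHORT = [
    (1, "EGFR", "c.2369C>T", "c.2369C>T"),
    (2, "EGFR", "c.2156G>C", "c.2156G>C"),
    (3, None, "", ""), (4, None, "", ""),
    (5, "EGFR", "Exon 20 INS", "c.2307_2308ins9"),
    (6, None, "", ""), (7, None, "", ""),
    (8, "EGFR", "c.2369C>T", "c.2369C>T"),
    (9, "EGFR", "c.2369C>T", "c.2369C>T"),
    (10, "EGFR", "Exon 19 DEL", "c.2236_2250del15"),
    (11, None, "", ""), (12, None, "", ""), (13, None, "", ""),
    (14, None, "", ""), (15, None, "", ""), (16, None, "", ""),
    (17, None, "", ""), (18, None, "", ""), (19, None, "", ""),
    (20, None, "", ""),
    (21, "KRAS", "c.35G>T", "c.35G>T"),
    (22, None, "", ""),
    (23, "EGFR", "c.2582T>A", "c.2582T>A"),
    (24, "EGFR", "c.2582T>A", "c.2582T>A"),
    (25, None, "", ""),
    (26, "BRAF", "c.1799T>A", "c.1799T>A"),
    (27, "KRAS", "c.34G>A", "c.34G>A"),
    (28, None, "", ""),
    (29, "EGFR", "c.2155G>A", "c.2155G>A"),
    (30, None, "", ""), (31, None, "", ""),
    (32, "KRAS", "c.34G>T", "c.34G>T"),
    (33, "BRAF", "c.1798_1799delGTinsAA", "c.1798_1799delGTinsAA"),
    (34, "BRAF", "c.1798_1799delGTinsAA", "c.1798_1799delGTinsAA"),
    (35, "EGFR", "Exon 19 DEL", "c.2235_2246del12"),
    (36, None, "", ""),
    (37, "EGFR", "c.2573T>G", "c.2573T>G"),
    (38, "EGFR", "c.2573T>G", "c.2573T>G"),
    (39, "KRAS", "c.34G>T", "c.34G>T"),
    (40, None, "", ""),
    (41, "KRAS", "c.38G>A", "c.38G>A"),
    (42, "KRAS", "c.38G>A", "c.38G>A"),
    (43, "EGFR", "c.2573T>G", None),  # variant below the panel's LoD
    (44, "EGFR", "Exon 20 INS", "c.2312_2314dupACC"),
    (45, None, "", ""), (46, None, "", ""),
    (47, "KRAS", "c.35G>T", "c.35G>T"),
    (48, None, "", ""), (49, None, "", ""),
    (50, "BRAF", "c.1799T>A", "c.1799T>A"),
    (51, "KRAS", "c.35G>A", "c.35G>A"),
    (52, "BRAF", "c.1799T>A", "c.1799T>A"),
    (53, "KRAS", "c.35G>T", "c.35G>T"),
    (54, "EGFR", "c.2573T>G", "c.2573T>G"),
    (55, "BRAF", "c.1799T>A", "c.1799T>A"),
]


def reference_cohort() -> tuple[list[ReferenceResult], list[ReferenceResult]]:
    """The 55-sample clinical cohort as (reference rows, panel-test rows).

    One positive or negative row per sample per queried gene; the single
    discordant sample is positive by the reference assay but negative by
    the panel (its variant sat below the panel's limit of detection).
    """
    reference, test = [], []
    for n, gene, ref_hgvs, test_hgvs in _COHORT:
        sample = f"DNA_{n:02d}"
        for g in CONCORDANCE_GENES:
            if gene == g:
                reference.append(ReferenceResult(sample, g, "positive", ref_hgvs))
                if test_hgvs is None:
                    test.append(ReferenceResult(sample, g, "negative"))
                else:
                    test.append(ReferenceResult(sample, g, "positive", test_hgvs))
            else:
                reference.append(ReferenceResult(sample, g, "negative"))
                test.append(ReferenceResult(sample, g, "negative"))
    return reference, test


# ---------------------------------------------------------------------------
# recurrent-variant blacklist
# ---------------------------------------------------------------------------

def recurrent_variant_blacklist() -> dict[VariantKey, str]:
    """Recurrent variants observed across unrelated samples, by class.

    Indel entries carry synthetic anchor alleles (the published list gives
    only "INS > T" / "DEL > A" display forms).
    """
    entries = [
        (_key("EGFR", 55249063, "A"), "HIGH_MAF_SNP"),
        (VariantKey("chr4", 1807894, "G", "A", "FGFR3"), "HIGH_MAF_SNP"),
        (VariantKey("chr13", 28610183, "T", "C", "FLT3"), "HIGH_MAF_SNP"),
        (VariantKey("chr4", 55141055, "A", "G", "PDGFRA"), "HIGH_MAF_SNP"),
        (VariantKey("chr5", 149433596, "A", "C", "CSF1R"), "END_OF_AMPLICON"),
        (VariantKey("chr5", 149433597, "C", "T", "CSF1R"), "END_OF_AMPLICON"),
        (VariantKey("chr19", 1220321, "T", "C", "STK11"), "HOMOPOLYMER"),
        (VariantKey("chr10", 89711834, "A", "AT", "PTEN"), "HOMOPOLYMER"),
        (VariantKey("chr13", 48953805, "CA", "C", "RB1"), "HOMOPOLYMER"),
    ]
    return dict(entries)


#: Global minor allele frequency of the exemplar common SNP (rs1050171).
RS1050171_MAF = 0.4183


# ---------------------------------------------------------------------------
# QC material (FFPE four-line mixture) baseline, n=10 runs
# ---------------------------------------------------------------------------

_QC_MATERIAL = [
    ("BRAF", 140453136, "A", 18.5, 1.5, 7.9),
    ("EGFR", 55242487, "T", 17.1, 1.4, 7.9),
    ("EGFR", 55249071, "T", 28.6, 1.7, 6.1),
    ("EGFR", 55259515, "G", 23.4, 1.5, 6.5),
    ("KRAS", 25398281, "A", 9.6, 0.7, 7.0),
    ("KRAS", 25398285, "T", 37.9, 1.1, 2.8),
    ("PIK3CA", 178952085, "G", 9.1, 1.0, 11.1),
    ("CTNNB1", 41266134, "DELCTT", 11.5, 2.0, 17.8),
]


def qc_material_stats() -> dict[VariantKey, tuple[float, float, float]]:
    """Published baseline (mean%, SD, CV%) per monitored variant."""
    return {_key(g, p, a): (m, s, cv) for g, p, a, m, s, cv in _QC_MATERIAL}


def qc_material_truth() -> ExpectedProfile:
    """Baseline mean VAFs of the QC material as a truth profile."""
    return ExpectedProfile({k: m for k, (m, _, _) in qc_material_stats().items()})


# ---------------------------------------------------------------------------
# dilution-series detection outcomes
# ---------------------------------------------------------------------------

def detection_outcomes() -> DetectionSeries:
    """Replicate detection outcomes of the fresh-frozen dilution series.

    Variants near 3% expected frequency were called in 9 of 10 replicate
    libraries; levels at and above 4% were called in every replicate —
    the series behind the assay's 4% limit of detection.
    """
    return DetectionSeries({3.0: (9, 10), 4.0: (10, 10), 8.0: (10, 10)})
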