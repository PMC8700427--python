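import pytest

from somamut.drivers import (CombinationCategory, build_profile,
                             classify_combinations, gene_sample_counts,
                             load_driver_table, pathway_scan,
                             recurrence_table)
from somamut.knowledge import OncoKbEffect
from somamut.pathogenicity import classify_all
from somamut.variants import PredictorCall, VariantClass
from .conftest import make_record

PATH5 = (PredictorCall.PATHOGENIC,) * 5


def classify(records, kb):
    return classify_all(records, kb)


def test_og_plus_tsg_is_combination(kb):
    records = [
        make_record(sample_id="T1", gene="KRAS",
                    variant_class=VariantClass.MISSENSE, votes=PATH5,
                    protein_change="p.G12V"),
        make_record(sample_id="T1", gene="NF1",
                    variant_class=VariantClass.NONSENSE),
    ]
    profile = build_profile("T1", classify(records, kb), kb)
    assert profile.og_genes == {"KRAS"}
    assert profile.tsg_genes == {"NF1"}
    assert profile.combination_category is CombinationCategory.COMBINATION
    assert profile.oncokb_effects["KRAS"] is OncoKbEffect.GAIN_OF_FUNCTION
    assert profile.ras_pik3ca_hit


def test_dual_only_sample_is_cgc_alone(kb):
    records = [make_record(sample_id="T1", gene="TP53",
                           variant_class=VariantClass.FRAMESHIFT, alt="-")]
    profile = build_profile("T1", classify(records, kb), kb)
    assert profile.dual_genes == {"TP53"}
    assert profile.combination_category is CombinationCategory.CGC_ALONE
    # several pathogenic variants in the same single gene stay cgc_alone
    records.append(make_record(sample_id="T1", gene="TP53",
                               variant_class=VariantClass.NONSENSE))
    profile = build_profile("T1", classify(records, kb), kb)
    assert profile.combination_category is CombinationCategory.CGC_ALONE


def test_two_dual_role_genes_form_a_combination(kb):
    records = [
        make_record(sample_id="T1", gene="TP53",
                    variant_class=VariantClass.NONSENSE),
        make_record(sample_id="T1", gene="NOTCH1",
                    variant_class=VariantClass.NONSENSE),
    ]
    profile = build_profile("T1", classify(records, kb), kb)
    assert profile.combination_category is CombinationCategory.COMBINATION


def test_no_cgc_sample_reports_ccgd_rank_a_putative_drivers(kb):
    records = [
        make_record(sample_id="T1", gene="HERC1",
                    variant_class=VariantClass.NONSENSE),
        make_record(sample_id="T1", gene="HUWE1", votes=PATH5),
        make_record(sample_id="T1", gene="AKAP9", votes=PATH5),  # rank B
    ]
    profile = build_profile("T1", classify(records, kb), kb)
    assert profile.combination_category is CombinationCategory.NO_CGC
    assert profile.putative_drivers == {"HERC1", "HUWE1"}


def test_putative_drivers_only_reported_without_cgc_genes(kb):
    records = [
        make_record(sample_id="T1", gene="TP53",
                    variant_class=VariantClass.NONSENSE),
        make_record(sample_id="T1", gene="HERC1",
                    variant_class=VariantClass.NONSENSE),
    ]
    profile = build_profile("T1", classify(records, kb), kb)
    assert profile.putative_drivers == set()


def test_exception_genes_are_excluded(kb):
    records = [
        make_record(sample_id="T1", gene="KIT", votes=PATH5),
        make_record(sample_id="T1", gene="TP53",
                    variant_class=VariantClass.NONSENSE),
    ]
    profile = build_profile("T1", classify(records, kb), kb,
                            exception_genes=["KIT"])
    assert profile.cgc_genes == {"TP53"}
    assert "KIT" in profile.benign_genes
    assert profile.combination_category is CombinationCategory.CGC_ALONE


def test_benign_variants_are_inert(kb):
    base = [
        make_record(sample_id="T1", gene="KRAS", votes=PATH5),
        make_record(sample_id="T1", gene="NF1",
                    variant_class=VariantClass.NONSENSE),
    ]
    benign_extras = [
        make_record(sample_id="T1", gene="MUC16", votes=()),  # 0 votes
        make_record(sample_id="T1", gene="BG1",
                    votes=(PredictorCall.PATHOGENIC,) * 2),  # non-census, 2 votes
    ]
    with_extras = build_profile("T1", classify(base + benign_extras, kb), kb)
    without = build_profile("T1", classify(base, kb), kb)
    for attr in ("og_genes", "tsg_genes", "dual_genes", "putative_drivers",
                 "ras_pik3ca_hit", "dna_repair_genes"):
        assert getattr(with_extras, attr) == getattr(without, attr)
    assert with_extras.combination_category is without.combination_category


def test_dna_repair_scan_includes_non_census_genes_and_excludes_tp53(kb):
    records = [
        make_record(sample_id="T1", gene="TP53",
                    variant_class=VariantClass.NONSENSE),
        make_record(sample_id="T1", gene="RAD50",
                    variant_class=VariantClass.FRAMESHIFT, alt="-"),
    ]
    profile = build_profile("T1", classify(records, kb), kb)
    assert profile.dna_repair_genes == {"RAD50"}  # RAD50 is not a census gene
    assert "TP53" not in profile.dna_repair_genes
    scan = pathway_scan({"g": [profile]})
    assert scan.loc["g", "dna_repair"] == 1
    assert scan.loc["g", "dna_repair_with_tp53"] == 1


def test_combination_counts_partition_every_fixture_cohort(fixture_profiles):
    table = classify_combinations(fixture_profiles)
    cats = [c.value for c in CombinationCategory]
    assert (table[cats].sum(axis=1) == table["n"]).all()
    assert classify_combinations({"empty": []}).loc["empty", cats].sum() == 0


def test_fixture_golden_driver_counts(fixture_profiles):
    """The bundled per-sample driver tables reproduce the published
    young-HGSOC breakdown: 14 combinations, 5 single-census samples, 2 with
    no census gene, 3 Ras-pathway samples and 4 DNA-repair samples."""
    table = classify_combinations(fixture_profiles)
    assert table.loc["young-HGSOC", "combination"] == 14
    assert table.loc["young-HGSOC", "cgc_alone"] == 5
    assert table.loc["young-HGSOC", "no_cgc"] == 2
    scan = pathway_scan({"young-HGSOC": fixture_profiles["young-HGSOC"]})
    assert scan.loc["young-HGSOC", "ras_pik3ca"] == 3
    assert scan.loc["young-HGSOC", "dna_repair"] == 4


def test_fixture_gene_recurrence_counts(fixture_profiles):
    young_hgsoc = gene_sample_counts(fixture_profiles["young-HGSOC"])
    assert young_hgsoc["TP53"] == 14
    elderly_tnbc = gene_sample_counts(fixture_profiles["elderly-TNBC"])
    assert elderly_tnbc["KMT2C"] == 6


def test_fixture_benign_occurrences_are_per_sample(fixture_profiles):
    """KIT is benign in one elderly-HGSOC sample but pathogenic in another;
    occurrence-level exclusion keeps the pathogenic one."""
    by_id = {p.sample_id: p for p in fixture_profiles["elderly-HGSOC"]}
    assert "KIT" in by_id["TCGA-04-1342-01"].og_genes
    assert "KIT" in by_id["TCGA-29-1702-01"].benign_genes
    assert "KIT" not in by_id["TCGA-29-1702-01"].og_genes


def test_every_sample_with_og_and_tsg_is_a_combination(fixture_profiles):
    for profiles in fixture_profiles.values():
        for p in profiles:
            if p.og_genes and p.tsg_genes:
                assert p.combination_category is CombinationCategory.COMBINATION


def test_recurrence_counts_samples_not_variants(kb):
    records = [
        make_record(sample_id="T1", gene="TP53",
                    variant_class=VariantClass.NONSENSE),
        make_record(sample_id="T1", gene="TP53", votes=PATH5),
        make_record(sample_id="T2", gene="TP53", votes=()),  # benign
        make_record(sample_id="T2", gene="TTN", votes=()),
    ]
    classified = {"g": classify(records, kb)}
    all_mode = recurrence_table(classified, kb, mode="all")
    assert all_mode.loc["TP53", "g"] == 2
    assert bool(all_mode.loc["TTN", "flags"])
    pathogenic_mode = recurrence_table(classified, kb, mode="pathogenic")
    assert pathogenic_mode.loc["TP53", "g"] == 1
    assert "TTN" not in pathogenic_mode.index
    with pytest.raises(ValueError):
        recurrence_table(classified, kb, mode="bogus")


def test_driver_table_loader_parses_glyphs(data_dir, kb):
    profiles = load_driver_table(data_dir / "drivers_young_hgsoc.tsv", kb)
    assert len(profiles) == 21
    by_id = {p.sample_id: p for p in profiles}
    first = by_id["TCGA-09-1664-01"]
    assert first.og_genes == {"KRAS"}
    assert first.oncokb_effects["KRAS"] is OncoKbEffect.GAIN_OF_FUNCTION
    assert first.oncokb_effects["NF1"] is OncoKbEffect.LIKELY_LOSS_OF_FUNCTION
    assert by_id["TCGA-29-1688-01"].benign_genes == {"HIP1"}
    putative = {p.sample_id: p.putative_drivers
                for p in load_driver_table(data_dir / "drivers_young_tnbc.tsv")}
    assert putative["BR078"] == {"HERC1", "HUWE1"}
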