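"""Simulator unit and calibration tests: genomes, mutations, meiosis, bulks."""

import numpy as np
import pytest

from bsamap.io import attach_truth, read_bulk_vcf, read_truth_table
from bsamap.simgenetics import (
    Bulk,
    Individual,
    SiteIndex,
    ToyGenome,
    VariantSite,
    add_background_variants,
    assign_phenotype,
    assign_phenotypes,
    build_bulk,
    cross,
    founders,
    make_causal_missense,
    make_toy_genome,
    mutagenize_ems,
    parse_scheme,
    run_pedigree,
    sample_ems_sites,
    sequence_bulks,
    translate_codon,
)


# ----------------------------------------------------------------- genomes


def test_toy_genome_deterministic_and_reproducible(tmp_path):
    a = make_toy_genome(1, 10_000, 1, seed=7)
    b = make_toy_genome(1, 10_000, 1, seed=7)
    assert a.chromosomes == b.chromosomes
    assert a.genes == b.genes
    fa1, fa2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
    a.to_fasta(fa1)
    b.to_fasta(fa2)
    assert fa1.read_bytes() == fa2.read_bytes()
    c = make_toy_genome(1, 10_000, 1, seed=8)
    assert c.chromosomes != a.chromosomes


def test_toy_genome_contract():
    g = make_toy_genome(5, 100_000, 20, seed=1)
    assert len(g.chromosomes) == 5
    assert len(g.genes) == 20
    assert {gene.strand for gene in g.genes} == {"+", "-"}
    for gene in g.genes:
        assert len(gene.exons) >= 2
        assert gene.cds_length % 3 == 0
        s, e = gene.span
        assert 1 <= s <= e <= g.length(gene.chrom)
        cds = gene.transcript_cds(g.sequence(gene.chrom))
        assert cds[:3] == "ATG"
        aas = [translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3)]
        assert aas[-1] == "*" and "*" not in aas[:-1]


@pytest.mark.parametrize("args", [(1, 100, 50), (1, 10_000, 500)])
def test_infeasible_gene_packing_raises(args):
    with pytest.raises(ValueError):
        make_toy_genome(*args, seed=0)


# --------------------------------------------------------------- mutations


def test_mutagenize_zero_rate_and_no_eligible_bases(small_genome):
    assert mutagenize_ems(small_genome, 0.0, seed=1) == []
    at_only = ToyGenome(chromosomes=(("chrA", "AT" * 5000),))
    assert mutagenize_ems(at_only, 0.5, seed=1) == []


def test_mutagenize_canonical_changes_and_binomial_count(small_genome):
    seq = small_genome.sequence("chr1")
    n_gc = seq.count("G") + seq.count("C")
    rate = 0.01
    counts = []
    for seed in range(1000):
        sites = mutagenize_ems(small_genome, rate, seed=seed)
        counts.append(len(sites))
    for s in mutagenize_ems(small_genome, rate, seed=0):
        assert (s.ref, s.alt) in (("G", "A"), ("C", "T"))
        assert s.origin == "EMS"
        assert small_genome.base_at(s.chrom, s.pos) == s.ref
    expected = n_gc * rate
    sigma_mean = np.sqrt(n_gc * rate * (1 - rate) / len(counts))
    assert abs(np.mean(counts) - expected) < 3 * sigma_mean


def test_background_variants_contract(small_genome):
    assert add_background_variants(small_genome, 0, seed=1) == []
    sites = add_background_variants(small_genome, 100, seed=1)
    assert len(sites) == 100
    assert len({(s.chrom, s.pos) for s in sites}) == 100
    assert all(s.origin == "background" and not s.is_causal for s in sites)
    # a sibling simulation sharing genome and seed reproduces the same set,
    # so a blacklist built from it removes them exactly
    sibling = add_background_variants(small_genome, 100, seed=1)
    assert {s.key for s in sibling} == {s.key for s in sites}
    with pytest.raises(ValueError):
        add_background_variants(small_genome, 10**7, seed=1)


def test_causal_missense_is_canonical_cds_change(small_genome):
    causal = make_causal_missense(small_genome)
    assert causal.is_causal and causal.origin == "EMS"
    assert (causal.ref, causal.alt) in (("G", "A"), ("C", "T"))
    gene = small_genome.genes[0]
    assert any(s <= causal.pos <= e for s, e, _ in gene.cds)


# ----------------------------------------------------------------- meiosis


def _one_site_index(genome):
    causal = make_causal_missense(genome)
    return SiteIndex(genome, [causal]), causal


def test_selfing_heterozygote_reproduces_1_2_1(small_genome):
    index, causal = _one_site_index(small_genome)
    founder, _ = founders(index)
    n = 40_000
    offspring = cross(founder, founder, n, seed=5)
    counts = {"0/0": 0, "0/1": 0, "1/1": 0}
    for ind in offspring:
        counts[ind.genotype_at(causal)] += 1
    for gt, p in (("0/0", 0.25), ("0/1", 0.5), ("1/1", 0.25)):
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(counts[gt] / n - p) < 3 * sigma


def test_backcross_heterozygote_transmits_half(small_genome):
    index, causal = _one_site_index(small_genome)
    founder, background = founders(index)
    n = 40_000
    offspring = cross(founder, background, n, seed=6)
    het = sum(ind.genotype_at(causal) == "0/1" for ind in offspring) / n
    assert abs(het - 0.5) < 3 * np.sqrt(0.25 / n)


def test_no_recombination_gametes_are_parental(small_genome):
    sites = sample_ems_sites(small_genome, 12, seed=4)
    index = SiteIndex(small_genome, sites)
    rng = np.random.default_rng(0)
    hap0 = rng.random(index.n_sites) < 0.5
    hap1 = rng.random(index.n_sites) < 0.5
    parent = Individual(index, hap0, hap1)
    blank = Individual(index, np.zeros(12, bool), np.zeros(12, bool))
    for child in cross(parent, blank, 50, crossover_rate=0.0, seed=9):
        assert (child.hap0 == hap0).all() or (child.hap0 == hap1).all()


def test_offspring_alleles_exist_in_parents(small_genome):
    sites = sample_ems_sites(small_genome, 20, seed=8)
    index = SiteIndex(small_genome, sites)
    rng = np.random.default_rng(2)
    a = Individual(index, rng.random(20) < 0.5, rng.random(20) < 0.5)
    b = Individual(index, rng.random(20) < 0.5, rng.random(20) < 0.5)
    union_a, union_b = a.hap0 | a.hap1, b.hap0 | b.hap1
    for child in cross(a, b, 200, crossover_rate=2.0, seed=3):
        assert not (child.hap0 & ~union_a).any()
        assert not (child.hap1 & ~union_b).any()


# ---------------------------------------------------------------- pedigree


def test_parse_scheme():
    assert parse_scheme("BC2S1") == ("backcross", "backcross", "self")
    assert parse_scheme("M2") == ("self",)
    assert parse_scheme("S1") == ("self",)
    for bad in ("", "XYZ", []):
        with pytest.raises(ValueError):
            parse_scheme(bad)


def test_bc2s1_segregates_three_quarters_wildtype(small_genome):
    index, causal = _one_site_index(small_genome)
    n = 4000
    result = run_pedigree("BC2S1", n, seed=21, index=index)
    population = assign_phenotypes(result.final, causal, seed=22)
    wt = sum(p.phenotype == "WT" for p in population) / n
    assert abs(wt - 0.75) < 3 * np.sqrt(0.75 * 0.25 / n)
    assert result.carrier.genotype_at(causal) == "0/1"


def test_self_only_scheme_segregates_1_2_1_at_every_ems_site(small_genome):
    causal = make_causal_missense(small_genome)
    passengers = sample_ems_sites(
        small_genome, 5, seed=31, exclude={(causal.chrom, causal.pos)}
    )
    index = SiteIndex(small_genome, [causal, *passengers])
    n = 4000
    result = run_pedigree("M2", n, seed=32, index=index)
    for site in index.sites:
        het = sum(i.genotype_at(site) == "0/1" for i in result.final) / n
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / n)


def test_unlinked_passenger_retention_in_bc2_is_one_quarter():
    # passengers on their own chromosomes are unlinked to the causal gene;
    # transmission through two backcrosses retains each with prob (1/2)^2
    genome = make_toy_genome(8, 10_000, 1, seed=41)
    causal = make_causal_missense(genome)
    passengers = []
    for i in range(2, 9):
        passengers += sample_ems_sites(genome, 1, seed=40 + i, chroms=[f"chr{i}"])
    index = SiteIndex(genome, [causal, *passengers])
    kept = total = 0
    for seed in range(60):
        result = run_pedigree("BC2S1", 1, seed=seed, index=index)
        for site in passengers:
            total += 1
            kept += result.carrier.genotype_at(site) == "0/1"
    p = 0.25
    assert abs(kept / total - p) < 3 * np.sqrt(p * (1 - p) / total)


# -------------------------------------------------------------- phenotypes


def test_heterozygote_phenotype_is_wildtype_ai_zero(small_genome):
    index, causal = _one_site_index(small_genome)
    founder, _ = founders(index)
    assert founder.genotype_at(causal) == "0/1"
    plant = assign_phenotype(founder, causal, seed=1)
    assert plant.phenotype == "WT"
    assert plant.flower_scores == (0,) * 10
    assert plant.plant_ai == 0.0


def test_mutant_phenotype_scores(small_genome):
    index, causal = _one_site_index(small_genome)
    hom = Individual(index, np.ones(1, bool), np.ones(1, bool))
    plant = assign_phenotype(hom, causal, (0, 0, 0, 1), n_flowers=10, seed=1)
    assert plant.phenotype == "mutant" and plant.plant_ai == 3.0
    dist = (0.1, 0.1, 0.2, 0.6)
    plant = assign_phenotype(hom, causal, dist, n_flowers=10_000, seed=2)
    mean, var = 2.3, 6.3 - 2.3**2
    assert abs(plant.plant_ai - mean) < 3 * np.sqrt(var / 10_000)


# ------------------------------------------------------------------- bulks


def _population(genome, n=300, seed=51):
    index, causal = _one_site_index(genome)
    result = run_pedigree("BC2S1", n, seed=seed, index=index)
    return assign_phenotypes(result.final, causal, seed=seed + 1), causal


def test_mutant_bulk_is_all_homozygous(small_genome):
    population, causal = _population(small_genome)
    bulk = build_bulk(population, "mutant", 30, "extreme-AI", seed=1)
    assert bulk.true_af(causal) == 1.0
    assert all(m.genotype_at(causal) == "1/1" for m in bulk.members)


def test_wt_bulk_composition_controls_true_af(small_genome):
    population, causal = _population(small_genome)
    bulk = build_bulk(population, "WT", 30, seed=2, causal=causal,
                      composition=(10, 20))
    assert bulk.true_af(causal) == pytest.approx(20 / 60)


def test_bulk_errors_and_determinism(small_genome):
    population, causal = _population(small_genome)
    with pytest.raises(ValueError, match="available"):
        build_bulk(population, "mutant", 10_000, seed=1)
    a = build_bulk(population, "mutant", 30, "extreme-AI", seed=7)
    b = build_bulk(population, "mutant", 30, "extreme-AI", seed=7)
    assert [id(m) for m in a.members] == [id(m) for m in b.members]
    with pytest.raises(ValueError):
        Bulk(tuple(population[:2]), "nonsense")


# -------------------------------------------------------------- sequencing


def _bulks(genome, seed=61):
    population, causal = _population(genome, seed=seed)
    mut = build_bulk(population, "mutant", 30, "extreme-AI", seed=seed)
    wt = build_bulk(population, "WT", 30, seed=seed + 1, causal=causal,
                    composition=(15, 15))
    return wt, mut, causal


def test_error_free_homozygous_bulk_af_is_exactly_one(small_genome):
    wt, mut, causal = _bulks(small_genome)
    result = sequence_bulks(wt, mut, [causal], mean_depth=45, error_rate=0.0,
                            seed=1)
    obs = result.observations[0]
    assert obs.mut.alt_reads == obs.mut.dp
    assert obs.mut.af == 1.0
    assert obs.mut.gt == "1/1"


def test_same_seed_gives_byte_identical_vcf(small_genome, tmp_path):
    wt, mut, causal = _bulks(small_genome)
    paths = []
    for name in ("a.vcf", "b.vcf"):
        result = sequence_bulks(wt, mut, [causal], seed=17)
        p = tmp_path / name
        result.write_vcf(p)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_single_heterozygote_deep_sequencing_af_near_half(small_genome):
    index, causal = _one_site_index(small_genome)
    founder, _ = founders(index)
    het = assign_phenotype(founder, causal, seed=1)
    hom = assign_phenotype(
        Individual(index, np.ones(1, bool), np.ones(1, bool)), causal, seed=2
    )
    wt = Bulk((het,), "WT")
    mut = Bulk((hom,), "mutant")
    result = sequence_bulks(wt, mut, [causal], mean_depth=10_000,
                            error_rate=0.0, seed=3)
    af = result.observations[0].wt.af
    assert abs(af - 0.5) < 3 * np.sqrt(0.25 / 10_000)


def test_observed_af_is_unbiased_for_error_adjusted_truth(small_genome):
    wt, mut, causal = _bulks(small_genome)
    error = 0.01
    p_true = wt.true_af(causal)
    p_adj = p_true * (1 - error) + (1 - p_true) * error
    afs = []
    for seed in range(1000):
        result = sequence_bulks(wt, mut, [causal], mean_depth=45,
                                error_rate=error, seed=seed)
        af = result.observations[0].wt.af
        if af is not None:
            afs.append(af)
    sigma_mean = np.sqrt(p_adj * (1 - p_adj) / 45 / len(afs))
    assert abs(np.mean(afs) - p_adj) < 3 * sigma_mean


def test_vcf_truth_roundtrip_is_exact(small_genome, tmp_path):
    causal = make_causal_missense(small_genome)
    passengers = sample_ems_sites(small_genome, 20, seed=5,
                                  exclude={(causal.chrom, causal.pos)})
    index = SiteIndex(small_genome, [causal, *passengers])
    ped = run_pedigree("BC2S1", 300, seed=62, index=index)
    population = assign_phenotypes(ped.final, index.causal, seed=63)
    mut = build_bulk(population, "mutant", 30, "extreme-AI", seed=64)
    wt = build_bulk(population, "WT", 30, seed=65)
    result = sequence_bulks(wt, mut, index.sites, seed=6)
    vcf, truth = tmp_path / "b.vcf", tmp_path / "t.tsv"
    result.write_vcf(vcf)
    result.write_truth(truth)
    back = attach_truth(read_bulk_vcf(vcf), read_truth_table(truth))
    assert back == result.observations


def test_empty_site_list_gives_empty_vcf_with_header(small_genome, tmp_path):
    wt, mut, _ = _bulks(small_genome)
    result = sequence_bulks(wt, mut, [], seed=1)
    assert result.observations == []
    p = tmp_path / "empty.vcf"
    result.write_vcf(p)
    text = p.read_text()
    assert text.startswith("##fileformat=VCFv4.2")
    assert read_bulk_vcf(p) == []
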