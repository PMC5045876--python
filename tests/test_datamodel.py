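"""Domain types, CSV round trips, and the packaged study fixture."""

import pytest

from ribarriers import (
    BarrierEstimate,
    CascadeResult,
    CrossingTable,
    MatingOutcome,
    SchemaError,
    SharingSummary,
    SpeciesAssemblage,
    SyntheticConfig,
    ValidationError,
    normalize_species,
    read_assemblage_table,
    read_barrier_table,
    read_crossing_table,
    write_assemblage_table,
    write_barrier_table,
    write_crossing_table,
)

CROSSING_HEADER = "population,plant_id,treatment,pollen_source,flowers,fruits"


class TestCrossingTable:
    def test_single_row_round_trip(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(f"{CROSSING_HEADER}\nCO,p1,open,CO,3,2\n")
        table = read_crossing_table(p)
        assert len(table) == 1
        assert table.total_fruits == 2
        out = tmp_path / "out.csv"
        write_crossing_table(table, out)
        assert read_crossing_table(out) == table

    def test_fruits_exceeding_flowers_rejected_with_row_number(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(f"{CROSSING_HEADER}\nCO,p1,open,CO,3,2\nCO,p2,open,CO,3,4\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_crossing_table(p)

    @pytest.mark.parametrize(
        "header",
        [
            "population,plant_id,treatment,pollen_source,flowers",  # missing column
            CROSSING_HEADER + ",extra",  # unknown column
        ],
    )
    def test_schema_violations_are_loud(self, tmp_path, header):
        p = tmp_path / "t.csv"
        n = len(header.split(","))
        p.write_text(header + "\n" + ",".join(["1"] * n) + "\n")
        with pytest.raises(SchemaError):
            read_crossing_table(p)

    def test_treatment_vocabulary_is_closed(self):
        with pytest.raises(ValidationError, match="treatment"):
            CrossingTable.from_records(
                [dict(population="CO", plant_id="p1", treatment="hand-self",
                      pollen_source="CO", flowers=3, fruits=1)]
            )

    def test_interspecific_requires_foreign_pollen(self):
        with pytest.raises(ValidationError, match="interspecific"):
            CrossingTable.from_records(
                [dict(population="CO", plant_id="p1", treatment="interspecific",
                      pollen_source="CO", flowers=3, fruits=1)]
            )

    def test_flowers_must_be_positive(self):
        with pytest.raises(ValidationError, match="flowers"):
            CrossingTable.from_records(
                [dict(population="CO", plant_id="p1", treatment="open",
                      pollen_source="CO", flowers=0, fruits=0)]
            )


class TestAssemblageTable:
    def test_one_assemblage_per_population_guild(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "population,guild,species,count\n"
            "CO,pollinator,Cynanthus sordidus,17\n"
            "CO,pollinator,Amazilia beryllina,34\n"
            "CO,pollinator,Amazilia violiceps,3\n"
            "CO,pollinator,Calothorax pulcher,1\n"
        )
        (a,) = read_assemblage_table(p)
        assert a.population == "CO" and a.guild == "pollinator"
        assert len(a.species) == 4
        assert a.total_count == 55

    def test_empty_file_with_header_gives_empty_list(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("population,guild,species,count\n")
        assert read_assemblage_table(p) == []

    def test_case_variants_merge_with_summed_counts(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "population,guild,species,count\n"
            "CO,pollinator,Amazilia  beryllina,3\n"
            "CO,pollinator,AMAZILIA BERYLLINA,2\n"
        )
        (a,) = read_assemblage_table(p)
        assert a.species == frozenset({"amazilia beryllina"})
        assert a.counts == {"amazilia beryllina": 5}

    def test_exact_duplicate_row_rejected(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "population,guild,species,count\n"
            "CO,pollinator,Amazilia beryllina,3\n"
            "CO,pollinator,Amazilia beryllina,3\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_assemblage_table(p)

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("population,guild,species,count\nCO,pollinator,x,-1\n")
        with pytest.raises(ValidationError, match="negative"):
            read_assemblage_table(p)

    def test_round_trip(self, tmp_path):
        assemblages = [
            SpeciesAssemblage("CO", "pollinator", frozenset({"a sp", "b sp"}), {"a sp": 3, "b sp": 1}),
            SpeciesAssemblage("AO", "host", frozenset({"c sp"})),
        ]
        p = tmp_path / "a.csv"
        write_assemblage_table(assemblages, p)
        back = read_assemblage_table(p)
        assert sorted((a.population, a.guild) for a in back) == [("AO", "host"), ("CO", "pollinator")]
        co = next(a for a in back if a.population == "CO")
        assert co.species == frozenset({"a sp", "b sp"}) and co.counts == {"a sp": 3, "b sp": 1}


def test_species_normalization_rules():
    assert normalize_species("  Amazilia   beryllina ") == "amazilia beryllina"


class TestDomainInvariants:
    @pytest.mark.parametrize("h,c", [(-0.1, 0.5), (0.5, 1.2)])
    def test_mating_outcome_bounds(self, h, c):
        with pytest.raises(ValidationError):
            MatingOutcome(h, c)

    def test_sharing_complement_enforced_for_computed_methods(self):
        with pytest.raises(ValidationError):
            SharingSummary(0.5, 0.6, method="count_jaccard")
        # direct method carries externally supplied values as-is
        SharingSummary(0.5, 0.6, method="direct")

    def test_barrier_stage_payload_pairing(self):
        sharing = SharingSummary(0.2, 0.8)
        outcome = MatingOutcome(0.2, 0.8)
        with pytest.raises(ValidationError):
            BarrierEstimate("x", "pre", 0.8, raw=outcome)
        with pytest.raises(ValidationError):
            BarrierEstimate("x", "post", 0.8, raw=sharing)

    def test_cascade_result_consistency_enforced(self):
        with pytest.raises(ValidationError):
            CascadeResult(order=("a",), strengths=(0.5,), absolute=(0.5,), relative=(1.0,), total=0.6)
        with pytest.raises(ValidationError):
            CascadeResult(order=("a",), strengths=(0.5,), absolute=(0.5,), relative=(0.5,), total=0.5)

    def test_counts_must_refer_to_member_species(self):
        with pytest.raises(ValidationError):
            SpeciesAssemblage("CO", "pollinator", frozenset({"a"}), {"b": 1})


class TestStudyFixture:
    """Raw values of the packaged worked example, exact at 3 decimals."""

    @pytest.mark.parametrize(
        "name,a,b",
        [
            ("Host species isolation", 0.200, 0.800),
            ("Seed dispersers isolation", 0.400, 0.600),
            ("Pollinator isolation", 0.800, 0.200),
        ],
    )
    def test_pre_barrier_raw_values(self, study, name, a, b):
        raw = study.barrier_raw(name)
        assert isinstance(raw, SharingSummary)
        assert (raw.shared_fraction, raw.unshared_fraction) == (a, b)

    @pytest.mark.parametrize(
        "name,h,c",
        [("CO Fruit set", 0.185, 0.814), ("AO Fruit set", 0.400, 0.600)],
    )
    def test_post_barrier_raw_values(self, study, name, h, c):
        raw = study.barrier_raw(name)
        assert isinstance(raw, MatingOutcome)
        assert (raw.heterospecific_success, raw.conspecific_success) == (h, c)

    def test_barrier_order_and_assemblage_sizes(self, study):
        assert [n for n, _, _ in study.barriers] == [
            "Host species isolation",
            "Seed dispersers isolation",
            "Pollinator isolation",
            "CO Fruit set",
            "AO Fruit set",
        ]
        assert len(study.assemblage("CO").species) == 4
        assert len(study.assemblage("AO").species) == 5


class TestBarrierTableIO:
    def test_round_trip(self, tmp_path, study):
        p = tmp_path / "b.csv"
        write_barrier_table(list(study.barriers), p)
        back = read_barrier_table(p)
        assert [(n, s) for n, s, _ in back] == [(n, s) for n, s, _ in study.barriers]
        assert back[0][2].shared_fraction == 0.200
        assert back[3][2].heterospecific_success == 0.185

    def test_header_must_match(self, tmp_path):
        p = tmp_path / "b.csv"
        p.write_text("name,stage,raw_a,raw_b\nx,pre,0.2,0.8\n")
        with pytest.raises(SchemaError):
            read_barrier_table(p)


class TestSyntheticConfig:
    def test_yaml_round_trip(self, tmp_path):
        from ribarriers import default_study_config

        cfg = default_study_config()
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert SyntheticConfig.from_yaml(p) == cfg

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(success_probs={"A": {"open": 1.5}}),
            dict(success_probs={"A": {"selfing": 0.5}}),
            dict(plant_sd=-1.0),
            dict(overlap_target={"pollinator": 2.0}),
            dict(species_pool={"pollinator": (-1, 4)}),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SyntheticConfig(**kwargs)
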