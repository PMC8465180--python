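import pytest

from degcord import core_model, homology, qpcr


@pytest.fixture(scope="session")
def table4_records():
    return core_model.load_fixture("table4")


@pytest.fixture(scope="session")
def table6_rows():
    return core_model.load_fixture("table6")


@pytest.fixture(scope="session")
def maps():
    return homology.default_maps()


@pytest.fixture(scope="session")
def classified_pairs(table4_records, maps):
    comparison = core_model.table6_comparison_records()
    return homology.classify_pairs(
        homology.pair_homologs(table4_records, comparison, maps)
    )


@pytest.fixture(scope="session")
def table5_samples():
    """Per-(gene, group) qPCR samples from the packaged table."""
    fx = core_model.load_fixture("table5")
    by: dict[tuple[str, str], list[qpcr.QPCRSample]] = {}
    for r in fx.rows:
        by.setdefault((r.gene, r.group), []).append(
            qpcr.QPCRSample(
                gene=r.gene,
                animal_id=r.animal_id,
                group=r.group,
                behavior_score=r.glove_score,
                rel_expr=r.rel_expr,
                nd_flag=r.nd_flag,
            )
        )
    return by


@pytest.fixture(scope="session")
def table8_fixture():
    return core_model.load_fixture("table8")


@pytest.fixture(scope="session")
def pair_rows(classified_pairs, table6_rows, maps):
    """Map each classified pair back to its row number in the 54-pair table."""
    import math

    def row_of(p):
        fsym = homology.normalize_symbol(p.focal.symbol, maps.alias_map)
        csym = homology.normalize_symbol(p.comparison.symbol)
        for r in table6_rows:
            if (
                homology.normalize_symbol(r.focal_symbol, maps.alias_map) == fsym
                and homology.normalize_symbol(r.comp_symbol) == csym
                and math.isclose(r.comp_log2fc, p.comparison.log2fc)
                and r.tissue == p.comparison.tissue
                and r.domestic_group == p.comparison.species
            ):
                return r.row
        raise AssertionError(f"pair {p} not found in the packaged table")

    return {p.pair_id: row_of(p) for p in classified_pairs}
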