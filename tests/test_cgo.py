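import pytest

from retroprev.cgo import (
    CancerGeneEntry,
    OrthogroupError,
    count_cgo,
    load_cancer_genes,
    parse_orthogroups,
)


def _write_tables(tmp_path, rows, counts_rows, species=("human", "spA", "spB")):
    groups = tmp_path / "Orthogroups.tsv"
    counts = tmp_path / "Orthogroups.GeneCount.tsv"
    header = "Orthogroup\t" + "\t".join(species)
    groups.write_text(header + "\n" + "\n".join(rows) + "\n")
    counts.write_text(header + "\tTotal\n" + "\n".join(counts_rows) + "\n")
    return groups, counts


def test_parse_orthogroups_consistent(tmp_path):
    g, c = _write_tables(
        tmp_path,
        ["OG0\tP1\tg1, g2\t", "OG1\tP2, P3\tg3\tg4"],
        ["OG0\t1\t2\t0\t3", "OG1\t2\t1\t1\t4"],
    )
    og = parse_orthogroups(g, c)
    assert og["OG0"]["members"]["spA"] == ["g1", "g2"]
    assert og["OG0"]["counts"] == {"human": 1, "spA": 2, "spB": 0}
    assert og["OG1"]["members"]["human"] == ["P2", "P3"]


def test_parse_orthogroups_count_mismatch(tmp_path):
    g, c = _write_tables(tmp_path, ["OG0\tP1\tg1, g2\t"], ["OG0\t1\t3\t0\t4"])
    with pytest.raises(OrthogroupError, match="OG0"):
        parse_orthogroups(g, c)


def test_parse_orthogroups_missing_id(tmp_path):
    g, c = _write_tables(tmp_path, ["OG0\tP1\tg1\t"], ["OG9\t1\t1\t0\t2"])
    with pytest.raises(OrthogroupError, match="identifiers mismatch"):
        parse_orthogroups(g, c)


def _entry(symbol, pid, role="oncogene", somatic=True, germline=False, fusion=False):
    return CancerGeneEntry(symbol, pid, somatic, germline, role, fusion)


def _og(tmp_path, rows, counts_rows):
    g, c = _write_tables(tmp_path, rows, counts_rows)
    return parse_orthogroups(g, c)


def test_count_cgo_basic_contribution(tmp_path):
    og = _og(tmp_path, ["OG0\tP1\tg1, g2\t"], ["OG0\t1\t2\t0\t3"])
    profile = count_cgo([_entry("MYC", "P1")], og, "spA", "human")
    assert (profile.total, profile.oncogene, profile.tsg) == (2, 2, 0)
    absent = count_cgo([_entry("MYC", "P1")], og, "spB", "human")
    assert absent.total == 0


def test_unassigned_gene_contributes_zero_and_is_logged(tmp_path):
    og = _og(tmp_path, ["OG0\tP1\tg1\t"], ["OG0\t1\t1\t0\t2"])
    log = []
    profile = count_cgo([_entry("TP53", "P999", role="tsg")], og, "spA", "human",
                        unresolved_log=log)
    assert profile.total == 0
    assert log == ["TP53"]


def test_shared_orthogroup_counts_per_gene_with_dedupe_switch(tmp_path):
    og = _og(tmp_path, ["OG0\tP1, P2\tg1, g2, g3\t"], ["OG0\t2\t3\t0\t5"])
    entries = [_entry("A", "P1"), _entry("B", "P2")]
    profile = count_cgo(entries, og, "spA", "human")
    assert profile.total == 6  # per-gene convention: 3 + 3
    deduped = count_cgo(entries, og, "spA", "human", dedupe=True)
    assert deduped.total == 3


def test_both_role_double_counts_oncogene_and_tsg(tmp_path):
    og = _og(tmp_path, ["OG0\tP1\tg1, g2\t"], ["OG0\t1\t2\t0\t3"])
    profile = count_cgo([_entry("ATM", "P1", role="both", germline=True)], og, "spA", "human")
    assert profile.oncogene == 2 and profile.tsg == 2
    assert profile.somatic == 2 and profile.germline == 2
    assert profile.oncogene + profile.tsg >= 2


def test_category_counts_never_exceed_total(tmp_path):
    og = _og(
        tmp_path,
        ["OG0\tP1\tg1, g2\t", "OG1\tP2\tg3\tg4, g5"],
        ["OG0\t1\t2\t0\t3", "OG1\t1\t1\t2\t4"],
    )
    entries = [
        _entry("A", "P1", role="both", fusion=True),
        _entry("B", "P2", role="tsg", somatic=False, germline=True),
    ]
    for sp in ("spA", "spB"):
        p = count_cgo(entries, og, sp, "human")
        for cat in ("somatic", "germline", "oncogene", "tsg", "fusion"):
            assert getattr(p, cat) <= p.total


def test_profiles_invariant_to_row_order(tmp_path):
    rows = ["OG0\tP1\tg1, g2\t", "OG1\tP2\tg3\tg4"]
    counts = ["OG0\t1\t2\t0\t3", "OG1\t1\t1\t1\t3"]
    (tmp_path / "a").mkdir()
    (tmp_path / "b").mkdir()
    og_fwd = _og(tmp_path / "a", rows, counts)
    og_rev = _og(tmp_path / "b", rows[::-1], counts[::-1])
    entries = [_entry("A", "P1"), _entry("B", "P2", role="tsg")]
    assert count_cgo(entries, og_fwd, "spA", "human") == count_cgo(
        entries, og_rev, "spA", "human"
    )


def test_load_cancer_genes(tmp_path):
    p = tmp_path / "genes.tsv"
    p.write_text(
        "symbol\tprotein_id\tsomatic\tgermline\trole\tfusion\n"
        "MYC\tP1\t1\t0\toncogene\t0\nATM\tP2\t1\t1\tboth\t1\n"
    )
    entries = load_cancer_genes(p)
    assert entries[0].somatic and not entries[0].germline
    assert entries[1].role == "both" and entries[1].fusion
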