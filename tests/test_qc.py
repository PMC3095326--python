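"""QC rules: region bounds, split-marker chimera screen, PCR-error collapse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycolib.qc import (
    CloneRecord,
    collapse_pcr_errors,
    detect_region_bounds,
    iupac_consensus,
    run_qc,
    screen_chimeras,
)
from mycolib.reference import ReferenceDB


def clone(seq, cid="c1", rs="M1S1R1", bounds=None):
    return CloneRecord(
        id=cid,
        sequence=seq,
        root_system=rs,
        sub_locality=rs[:4],
        main_locality=rs[:2],
        region_bounds=bounds,
    )


# ---------------------------------------------------------------------------
# region bounds


def test_bounds_recover_generator_truth(default_community, default_library):
    records, _ = default_library
    profile = default_community.conserved_5p8s
    truth_bounds = default_community.region_bounds()
    for r in records[:40]:
        assert detect_region_bounds(r.sequence, profile) == truth_bounds


def test_bounds_robust_to_substitutions_inside_58s(default_community, rng):
    """Two substitutions inside the conserved core must not move the best
    window; checked against a brute-force best-window scan."""
    profile = default_community.conserved_5p8s
    seq = default_community.references["sequence"].iloc[3]
    a, b = default_community.region_bounds()
    mutated = list(seq)
    for p in (a + 10, a + 100):
        mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
    mutated = "".join(mutated)
    got = detect_region_bounds(mutated, profile)
    # brute-force scan oracle
    w = len(profile)
    scores = [
        sum(x == y for x, y in zip(mutated[i : i + w], profile))
        for i in range(len(mutated) - w + 1)
    ]
    start = int(np.argmax(scores))
    assert got == (start, start + w) == (a, b)


def test_random_sequence_is_unsplittable(rng):
    profile = "".join(rng.choice(list("ACGT"), 160))
    seq = "".join(rng.choice(list("ACGT"), 490))
    assert detect_region_bounds(seq, profile) is None


# ---------------------------------------------------------------------------
# chimera screen


def make_refdb():
    rng = np.random.default_rng(0)
    rows = []
    core = "".join(rng.choice(list("ACGT"), 40))
    for i, genus in enumerate(["gA", "gA", "gB", "gC"]):
        its1 = "".join(rng.choice(list("ACGT"), 50))
        its2 = "".join(rng.choice(list("ACGT"), 60))
        rows.append(
            {
                "ref_id": f"R{i}",
                "sequence": its1 + core + its2,
                "species": f"sp{i}",
                "genus": genus,
                "family": "fX",
                "its1_end": 50,
                "fivep8s_end": 90,
            }
        )
    return ReferenceDB(pd.DataFrame(rows))


def test_junction_chimera_between_genera_is_flagged():
    db = make_refdb()
    s0, s2 = db.table["sequence"][0], db.table["sequence"][2]
    chimera = s0[:50] + s2[50:]
    report = screen_chimeras([clone(chimera, bounds=(50, 90))], db)
    assert report["is_chimera"].iloc[0]


def test_consistent_regions_pass():
    db = make_refdb()
    report = screen_chimeras([clone(db.table["sequence"][3], bounds=(50, 90))], db)
    assert not report["is_chimera"].iloc[0]


def test_within_genus_chimera_passes_the_genus_rule():
    db = make_refdb()
    s0, s1 = db.table["sequence"][0], db.table["sequence"][1]
    chimera = s0[:50] + s1[50:]
    report = screen_chimeras([clone(chimera, bounds=(50, 90))], db)
    assert not report["is_chimera"].iloc[0]


def test_replicated_sequence_auto_passes_even_if_chimeric():
    db = make_refdb()
    s0, s2 = db.table["sequence"][0], db.table["sequence"][2]
    chimera = s0[:50] + s2[50:]
    records = [
        clone(chimera, "c1", "M1S1R1", bounds=(50, 90)),
        clone(chimera, "c2", "M1S2R1", bounds=(50, 90)),
    ]
    report = screen_chimeras(records, db)
    assert not report["is_chimera"].any()
    assert (report["note"] == "replicated_across_root_systems").all()


def test_low_identity_region_is_a_no_call(rng):
    db = make_refdb()
    random_seq = "".join(rng.choice(list("ACGT"), 160))
    report = screen_chimeras([clone(random_seq, bounds=(50, 90))], db)
    assert not report["is_chimera"].iloc[0]
    assert report["note"].iloc[0] == "no_call_low_identity"


def test_empty_reference_db_is_an_error():
    with pytest.raises(ValueError):
        ReferenceDB(pd.DataFrame())


def test_screen_matches_truth_on_synthetic_library(default_library, default_reference):
    records, truth = default_library
    report = screen_chimeras(records, default_reference)
    flagged = set(report.loc[report["is_chimera"], "clone_id"])
    assert flagged == truth.chimera_ids()


# ---------------------------------------------------------------------------
# PCR-error collapse


def test_singleton_merges_into_replicated_sequence():
    records = [clone("ACGT", f"c{i}") for i in range(3)] + [clone("ACTT", "c3")]
    genos, status = collapse_pcr_errors(records)
    assert len(genos) == 1
    assert genos[0].sequence == "ACGT"
    assert sorted(genos[0].members) == ["c0", "c1", "c2", "c3"]
    assert status.set_index("clone_id").loc["c3", "status"] == "collapsed"


def test_two_lone_clones_become_iupac_consensus():
    genos, status = collapse_pcr_errors([clone("ACGT", "c1"), clone("ACTT", "c2")])
    assert len(genos) == 1
    assert genos[0].sequence == "ACKT"  # G/T -> K
    assert (status["status"] == "consensus_member").all()


def test_iupac_consensus_codes():
    assert iupac_consensus("ACGT", "ACGT") == "ACGT"
    assert iupac_consensus("C", "T") == "Y"
    assert iupac_consensus("A", "G") == "R"


def test_three_differences_stay_distinct():
    records = [clone("AAAAAAAA", f"c{i}") for i in range(2)] + [clone("AAATTTAA", "c9")]
    genos, _ = collapse_pcr_errors(records)
    assert sorted(g.sequence for g in genos) == ["AAAAAAAA", "AAATTTAA"]


def test_length_differing_sequences_never_collapse():
    genos, _ = collapse_pcr_errors([clone("ACGT", "c1"), clone("ACG", "c2")])
    assert len(genos) == 2


def test_collapse_requires_one_root_system():
    with pytest.raises(ValueError):
        collapse_pcr_errors([clone("ACGT", "a", "M1S1R1"), clone("ACGT", "b", "M1S1R2")])


@settings(max_examples=40, deadline=None)
@given(
    st.lists(
        st.text(alphabet="ACGT", min_size=6, max_size=6),
        min_size=1,
        max_size=12,
    )
)
def test_collapse_is_idempotent_and_conserves_clones(seqs):
    records = [clone(s, f"c{i}") for i, s in enumerate(seqs)]
    genos, _ = collapse_pcr_errors(records)
    assert sum(len(g.members) for g in genos) == len(records)
    # feed the collapsed genotypes back in (one pseudo-clone per member)
    again = [
        clone(g.sequence, f"r{i}_{j}")
        for i, g in enumerate(genos)
        for j in range(len(g.members))
    ]
    genos2, _ = collapse_pcr_errors(again)
    assert sorted((g.sequence, len(g.members)) for g in genos) == sorted(
        (g.sequence, len(g.members)) for g in genos2
    )


# ---------------------------------------------------------------------------
# full QC pass


def test_qc_conserves_clones(default_library, default_qc):
    records, _ = default_library
    n_members = sum(len(v) for v in default_qc.genotypes.members.values())
    assert n_members + default_qc.n_chimeric == len(records)
    assert len(default_qc.clone_status) == len(records)


def test_noise_free_qc_reproduces_true_genotypes(noise_free_setup, default_reference):
    cfg, community, records, truth = noise_free_setup
    result = run_qc(records, ReferenceDB.from_metacommunity(community))
    true_genos = set()
    for _, row in truth.clones.iterrows():
        vidx = int(row["genotype"].split(".v")[1])
        true_genos.add(community.variants[row["otu"]][vidx])
    assert set(result.genotypes.table["sequence"]) == true_genos
    assert result.n_chimeric == 0
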