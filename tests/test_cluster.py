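"""OTU clustering: linkage semantics, recovery, naming thresholds."""

import numpy as np
import pandas as pd
import pytest

from mycolib.cluster import (
    OTUClusterer,
    assign_names,
    cluster_otus,
    identity_matrix,
    rank_for_identity,
)
from mycolib.reference import ReferenceDB
from oracles import single_linkage_components


def mutate(seq, k, rng):
    pos = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([c for c in "ACGT" if c != out[p]])
    return "".join(out)


def partition(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return sorted(groups.values(), key=sorted)


def test_near_identical_sequences_form_one_otu(rng):
    base = "".join(rng.choice(list("ACGT"), 300))
    seqs = [base, mutate(base, 2, rng), mutate(base, 3, rng)]
    assert OTUClusterer().fit(seqs).n_clusters_ == 1


def test_divergent_sequences_stay_apart(rng):
    base = "".join(rng.choice(list("ACGT"), 300))
    seqs = [base, mutate(base, 30, rng)]  # 90% identity < 0.97
    assert OTUClusterer(threshold=0.97).fit(seqs).n_clusters_ == 2


def test_chain_linkage_single_vs_greedy(rng):
    """a-b and b-c just above threshold, a-c below: single linkage chains
    them into one OTU, greedy centroid clustering keeps two."""
    n = 400
    base = "".join(rng.choice(list("ACGT"), n))
    b = base
    a = mutate(b, 8, rng)  # 98% to b
    pos_free = [i for i in range(n) if a[i] == b[i]]
    c = list(b)
    for p in rng.choice(pos_free, size=8, replace=False):
        c[p] = rng.choice([x for x in "ACGT" if x != c[p]])
    c = "".join(c)  # 98% to b, ~96% to a
    mat = identity_matrix([a, b, c])
    assert mat[0, 1] >= 0.97 and mat[1, 2] >= 0.97 and mat[0, 2] < 0.97
    single = OTUClusterer(linkage="single").fit([a, b, c])
    # abundance order a > b > c: a founds the first centroid, b joins it,
    # c (96% to a) founds its own
    greedy = OTUClusterer(linkage="greedy").fit([a, b, c], abundances=[3, 2, 1])
    assert single.n_clusters_ == 1
    assert greedy.n_clusters_ == 2
    # oracle check on the same instance
    comps = single_linkage_components(mat, 0.97)
    assert len(comps) == single.n_clusters_


@pytest.mark.parametrize("instance_seed", range(12))
def test_single_linkage_equals_brute_force_components(instance_seed):
    """Random mutation-structured instances of <=10 sequences: the partition
    must equal the connected components of the dense identity graph."""
    rng = np.random.default_rng(instance_seed)
    n_anc = rng.integers(1, 4)
    ancestors = ["".join(rng.choice(list("ACGT"), 150)) for _ in range(n_anc)]
    seqs = []
    for _ in range(rng.integers(3, 11)):
        anc = ancestors[rng.integers(n_anc)]
        seqs.append(mutate(anc, int(rng.integers(0, 7)), rng))
    seqs = list(dict.fromkeys(seqs))  # dereplicate
    labels = OTUClusterer(threshold=0.97).fit(seqs).labels_
    mat = identity_matrix(seqs)
    comps = sorted(single_linkage_components(mat, 0.97), key=sorted)
    assert partition(labels) == comps


def test_otu_count_non_increasing_as_threshold_drops(rng):
    base = "".join(rng.choice(list("ACGT"), 200))
    seqs = [mutate(base, int(k), rng) for k in rng.integers(0, 30, size=8)]
    seqs = list(dict.fromkeys(seqs))
    counts = [
        OTUClusterer(threshold=t).fit(seqs).n_clusters_
        for t in (0.99, 0.97, 0.93, 0.88, 0.5)
    ]
    assert counts == sorted(counts, reverse=True)


def test_single_linkage_invariant_to_input_permutation(rng):
    base = "".join(rng.choice(list("ACGT"), 200))
    seqs = list(dict.fromkeys(mutate(base, int(k), rng) for k in rng.integers(0, 25, size=9)))
    ref_partition = None
    for perm_seed in range(3):
        order = np.random.default_rng(perm_seed).permutation(len(seqs))
        shuffled = [seqs[i] for i in order]
        labels = OTUClusterer().fit(shuffled).labels_
        part = sorted(
            sorted(shuffled[i] for i in grp) for grp in partition(labels)
        )
        if ref_partition is None:
            ref_partition = part
        assert part == ref_partition


def test_invalid_threshold_rejected():
    with pytest.raises(ValueError):
        OTUClusterer(threshold=1.5).fit(["ACGT"])


def test_perfect_recovery_on_well_separated_community(noise_free_setup):
    """Intra-OTU divergence <1%, inter-OTU >6.5% ITS floor: the recovered
    OTU partition equals the truth partition of sampled genotypes."""
    from mycolib.qc import run_qc
    from mycolib.reference import ReferenceDB

    cfg, community, records, truth = noise_free_setup
    qc = run_qc(records, ReferenceDB.from_metacommunity(community))
    otus = cluster_otus(qc.genotypes, ReferenceDB.from_metacommunity(community))
    assert otus.n_otus == truth.incidence().shape[0]
    # every recovered OTU's member genotypes map to exactly one true OTU
    seq_to_true = {
        v: otu for otu, vs in community.variants.items() for v in vs
    }
    gid_to_seq = dict(
        zip(qc.genotypes.table["genotype_id"], qc.genotypes.table["sequence"])
    )
    for _, row in otus.assignments.iterrows():
        true_otus = {seq_to_true[gid_to_seq[g]] for g in row["members"].split(",")}
        assert len(true_otus) == 1


def make_named_refdb(rng):
    rows = []
    for i in range(3):
        rows.append(
            {
                "ref_id": f"R{i}",
                "sequence": "".join(rng.choice(list("ACGT"), 200)),
                "species": f"Examplea specifica{i}",
                "genus": f"Examplea{i}",
                "family": f"Exampleaceae{i}",
                "its1_end": 60,
                "fivep8s_end": 120,
            }
        )
    return ReferenceDB(pd.DataFrame(rows))


@pytest.mark.parametrize(
    "n_diffs,rank", [(4, "species"), (16, "genus"), (36, "family_or_order")]
)
def test_similarity_rank_thresholds(n_diffs, rank, rng):
    """98% -> species name, 92% -> genus 'sp.N', 82% -> family label."""
    db = make_named_refdb(rng)
    query = mutate(db.table["sequence"][1], n_diffs, rng)
    named = assign_names([query], db)
    assert named["rank"].iloc[0] == rank
    if rank == "species":
        assert named["name"].iloc[0] == "Examplea specifica1"
    elif rank == "genus":
        assert named["name"].iloc[0] == "Examplea1 sp.1"
    else:
        assert named["name"].iloc[0].startswith("Exampleaceae")


def test_rank_boundaries_are_literal():
    assert rank_for_identity(0.97) == "species"
    assert rank_for_identity(0.9699) == "genus"
    assert rank_for_identity(0.90) == "genus"
    assert rank_for_identity(0.8999) == "family_or_order"


def test_duplicate_species_names_get_numbered(rng):
    db = make_named_refdb(rng)
    base = db.table["sequence"][0]
    named = assign_names([mutate(base, 2, rng), mutate(base, 3, rng)], db)
    assert list(named["name"]) == ["Examplea specifica0 1", "Examplea specifica0 2"]
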