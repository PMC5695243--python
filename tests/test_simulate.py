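"""Generator invariants: determinism, truth manifests, read statistics."""

import numpy as np
import pytest

from ndhscan.annotate import classify_sample
from ndhscan.core import revcomp
from ndhscan.simulate import (DegradationSpec, TruthManifest,
                              apply_degradations, build_chondriome,
                              cymbidium_like, make_reference, simulate_reads)


def test_make_reference_deterministic():
    a = make_reference(seed=5)
    b = make_reference(seed=5)
    assert a.plastome.seq == b.plastome.seq
    assert a.region.seq == b.region.seq
    assert make_reference(seed=6).plastome.seq != a.plastome.seq


def test_reference_gene_lengths_match_config(reference):
    from ndhscan.simulate import DEFAULT_GENE_LENGTHS
    for gene, L in DEFAULT_GENE_LENGTHS.items():
        assert len(reference.genes[gene].cds) == L


def test_reference_cds_are_intact_orfs(reference):
    from ndhscan.core import translate
    for gene, model in reference.genes.models.items():
        prot = translate(model.cds)
        assert prot.startswith("M") and prot.endswith("*")
        assert "*" not in prot[:-1], gene


def test_reference_invalid_lengths_rejected():
    with pytest.raises(ValueError):
        make_reference(gene_lengths={"ndhE": 301})  # not divisible by 3
    with pytest.raises(ValueError):
        make_reference(gene_lengths={"ndhE": 30})


def test_ir_mirror_contains_ndhB_twice(reference):
    b = reference.genes["ndhB"]
    exon1 = reference.plastome.seq[b.exons[0][0] - 1:b.exons[0][1]]
    seq = reference.plastome.seq
    assert seq.count(exon1) == 1 and seq.count(revcomp(exon1)) == 1


def test_empty_spec_list_is_identity(reference):
    ref_out, mutated, manifest = apply_degradations(reference, [], seed=0)
    assert mutated.seq == reference.plastome.seq
    assert manifest.events == []
    assert set(manifest.expected_classes.values()) == {1}


def test_overlapping_structural_operators_rejected(reference):
    specs = [DegradationSpec("ndhG", "truncate", {"fraction": 0.6}),
             DegradationSpec("ndhG", "truncate", {"fraction": 0.3})]
    with pytest.raises(ValueError, match="overlapping"):
        apply_degradations(reference, specs, seed=0)


def test_manifest_round_trips_through_json(preset):
    text = preset.manifest.to_json()
    back = TruthManifest.from_json(text)
    assert back.to_json() == text
    assert back.expected_classes == preset.manifest.expected_classes


def test_planting_edits_confined_to_spacers(preset, reference):
    """The analysis reference differs from the pristine genome only at
    planted repeat/AT spacer positions; every gene stays class 1-identical."""
    calls = classify_sample(preset.reference.plastome,
                            preset.reference.genes)
    assert all(c.cls == 1 for c in calls.values())


def test_chondriome_segments_recorded_exactly():
    ref = make_reference(seed=3)
    segs = [((1000, 3000), False), ((5000, 6500), True)]
    mt, manifest = build_chondriome(ref.plastome, segs, backbone_len=20000,
                                    seed=3, divergence=0.0)
    for entry in manifest.mt_segments:
        s, e = entry["mt_interval"]
        assert mt.seq[s - 1:e] == entry["seq"]
    # non-inverted, divergence-free copy equals the plastome source
    first = manifest.mt_segments[0]
    ps, pe = first["plastome_interval"]
    assert first["seq"] == ref.plastome.seq[ps - 1:pe]
    # inverted segment records the internal inversion interval
    second = manifest.mt_segments[1]
    assert second["inverted"] and "inversion_segment_interval" in second


def test_chondriome_empty_segment_list_is_pure_backbone():
    ref = make_reference(seed=4)
    mt, manifest = build_chondriome(ref.plastome, [], backbone_len=5000,
                                    seed=4)
    assert len(mt.seq) == 5000 and manifest.mt_segments == []


def test_simulated_depth_ratio_tracks_copy_number():
    ref = make_reference(seed=8)
    mt, _ = build_chondriome(ref.plastome, [], backbone_len=30000, seed=8)
    pairs, _ = simulate_reads([(ref.plastome, 10.0), (mt, 1.0)],
                              n_pairs=20000, seed=8)
    n_pt = sum(p.read1.seq in ref.plastome.seq for p in pairs)
    n_mt = len(pairs) - n_pt
    expect_ratio = 10.0 * len(ref.plastome.seq) / (1.0 * len(mt.seq))
    assert n_pt / n_mt == pytest.approx(expect_ratio, rel=0.10)


def test_error_free_reads_are_exact_substrings():
    ref = make_reference(seed=9)
    pairs, _ = simulate_reads([(ref.plastome, 1.0)], n_pairs=200, seed=9)
    g = ref.plastome.seq
    for p in pairs:
        assert p.read1.seq in g
        assert revcomp(p.read2.seq) in g
        assert p.read1.quality == [40] * len(p.read1.seq)


def test_reads_deterministic_under_seed():
    ref = make_reference(seed=10)
    a, _ = simulate_reads([(ref.plastome, 1.0)], n_pairs=50, seed=1)
    b, _ = simulate_reads([(ref.plastome, 1.0)], n_pairs=50, seed=1)
    assert [(p.read1.seq, p.read2.seq) for p in a] == \
        [(p.read1.seq, p.read2.seq) for p in b]


def test_error_rate_marks_qualities():
    ref = make_reference(seed=11)
    pairs, _ = simulate_reads([(ref.plastome, 1.0)], n_pairs=300,
                              error_rate=0.02, seed=11)
    g = ref.plastome.seq
    n_err = sum(q == 13 for p in pairs for q in p.read1.quality)
    n_tot = sum(len(p.read1.seq) for p in pairs)
    assert n_err / n_tot == pytest.approx(0.02, rel=0.25)
    mismatched = [p for p in pairs if p.read1.seq not in g]
    assert mismatched  # errors really change sequence


def test_insert_mean_validation():
    ref = make_reference(seed=12)
    with pytest.raises(ValueError):
        simulate_reads([(ref.plastome, 1.0)], read_len=100,
                       insert=(150, 10), n_pairs=10)
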