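import random

import pytest

from chemlex import (
    Annotation, ConfusionCounts, EntityClass, GoldAnnotation, build_index,
    build_keyword_table, categorize_errors, compute_metrics, disambiguate,
    find_matches, per_class_recall, read_gold, round_half_up, score,
)
from chemlex.evaluation import write_gold
from conftest import make_concept, make_dictionary


def ann(doc_id, start, end, surface="x", status="kept"):
    return Annotation(doc_id, start, end, surface, surface, frozenset({"C1"}),
                      status=status)


def gold(doc_id, start, end, surface="x", cls=EntityClass.TRIV):
    return GoldAnnotation(doc_id, start, end, surface, cls)


# ---------------------------------------------------------------------------
# gold I/O
# ---------------------------------------------------------------------------

def test_read_gold_round_trip(tmp_path):
    (tmp_path / "d0.txt").write_text("aspirin and caffeine were given")
    golds = [
        GoldAnnotation("d0", 0, 7, "aspirin", EntityClass.TRIV),
        GoldAnnotation("d0", 12, 20, "caffeine", EntityClass.TRIV),
    ]
    write_gold(golds, tmp_path)
    docs, read_back = read_gold(tmp_path)
    assert docs == {"d0": "aspirin and caffeine were given"}
    assert sorted(read_back, key=lambda g: g.start) == golds


def test_read_gold_surface_mismatch_errors(tmp_path):
    (tmp_path / "d0.txt").write_text("aspirin was given")
    (tmp_path / "d0.ann").write_text("T1\tTRIV 0 7\tcaffeine\n")
    with pytest.raises(ValueError, match="surface mismatch"):
        read_gold(tmp_path)


def test_read_gold_unknown_class_errors(tmp_path):
    (tmp_path / "d0.txt").write_text("aspirin was given")
    (tmp_path / "d0.ann").write_text("T1\tDRUG 0 7\taspirin\n")
    with pytest.raises(ValueError, match="unknown entity class"):
        read_gold(tmp_path)


def test_doc_without_ann_file_has_no_gold(tmp_path):
    (tmp_path / "d0.txt").write_text("nothing chemical here")
    docs, golds = read_gold(tmp_path)
    assert docs and golds == []


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def test_identical_spans_all_tp():
    preds = [ann("d0", i, i + 2) for i in range(0, 10, 2)]
    golds = [gold("d0", i, i + 2) for i in range(0, 10, 2)]
    assert score(preds, golds) == ConfusionCounts(5, 0, 0)


def test_off_by_one_is_fp_plus_fn():
    assert score([ann("d0", 0, 5)], [gold("d0", 0, 6)]) == ConfusionCounts(0, 1, 1)


def test_removed_predictions_do_not_score():
    preds = [ann("d0", 0, 5, status="removed_by_disambiguation")]
    assert score(preds, [gold("d0", 0, 5)]) == ConfusionCounts(0, 0, 1)


def test_prediction_in_gold_free_document_is_fp():
    assert score([ann("d9", 0, 5)], [gold("d0", 0, 5)]) == ConfusionCounts(0, 1, 1)


@pytest.mark.parametrize("seed", range(10))
def test_score_equals_brute_force_set_comparison(seed):
    rng = random.Random(seed)
    preds = {("d0", a, a + rng.randint(1, 4)) for a in rng.sample(range(40), 8)}
    golds = {("d0", a, a + rng.randint(1, 4)) for a in rng.sample(range(40), 8)}
    c = score(
        [ann(*p) for p in preds],
        [gold(*g) for g in golds],
    )
    assert c.tp == len(preds & golds)
    assert c.fp == len(preds - golds)
    assert c.fn == len(golds - preds)
    assert c.tp + c.fn == len(golds) and c.tp + c.fp == len(preds)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_f_score_from_printed_precision_recall():
    p, r = 0.87, 0.19
    f = 2 * p * r / (p + r)
    assert round_half_up(f) == 0.31


def test_harmonic_mean_identity():
    c = ConfusionCounts(3, 1, 1)  # P = R = 0.75
    p, r, f = compute_metrics(c)
    assert p == r == f == 0.75


def test_hand_arithmetic():
    p, r, f = compute_metrics(ConfusionCounts(2, 1, 2))
    assert round_half_up(p, 3) == 0.667
    assert round_half_up(r, 3) == 0.500
    assert round_half_up(f, 3) == 0.571


def test_zero_denominator_conventions():
    assert compute_metrics(ConfusionCounts(0, 0, 0)) == (0.0, 0.0, 0.0)
    assert compute_metrics(ConfusionCounts(0, 0, 5)) == (0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# per-class recall
# ---------------------------------------------------------------------------

def test_per_class_recall_all_matched():
    golds = [gold("d0", i, i + 2) for i in range(0, 6, 2)]
    preds = [ann("d0", i, i + 2) for i in range(0, 6, 2)]
    out = per_class_recall(preds, golds)
    assert out[EntityClass.TRIV] == 1.0
    assert out[EntityClass.IUPAC] is None  # absent from gold: undefined


def test_per_class_recall_no_predictions():
    golds = [gold("d0", 0, 2, cls=EntityClass.SUM), gold("d0", 4, 6, cls=EntityClass.ABB)]
    out = per_class_recall([], golds)
    assert out[EntityClass.SUM] == 0.0 and out[EntityClass.ABB] == 0.0


def test_weighted_class_recalls_reconstruct_overall():
    rng = random.Random(4)
    golds, preds = [], []
    pos = 0
    for i in range(30):
        cls = rng.choice(list(EntityClass))
        golds.append(gold("d0", pos, pos + 3, cls=cls))
        if rng.random() < 0.6:
            preds.append(ann("d0", pos, pos + 3))
        pos += 5
    counts = score(preds, golds)
    _, overall_recall, _ = compute_metrics(counts)
    rec = per_class_recall(preds, golds)
    sizes = {
        cls: sum(1 for g in golds if g.entity_class is cls) for cls in EntityClass
    }
    weighted = sum(
        rec[cls] * sizes[cls] for cls in EntityClass if rec[cls] is not None
    ) / len(golds)
    assert weighted == pytest.approx(overall_recall)


# ---------------------------------------------------------------------------
# error categorization
# ---------------------------------------------------------------------------

def _pipeline_artifacts(d, doc, cfg=None):
    from chemlex import FilterConfig, apply_removal_rules, apply_rewrite_rules

    cfg = cfg or FilterConfig()
    filtered, log = apply_removal_rules(d, cfg)
    filtered, _ = apply_rewrite_rules(filtered)
    idx = build_index(filtered)
    pre = find_matches(doc, idx, doc_id="d0")
    kt = build_keyword_table(filtered)
    post = disambiguate(pre, doc, filtered, kt, idx=idx)
    kept = [a for a in post if a.status == "kept"]
    return d, filtered, pre, log, kept


def test_fn_partial_match_category():
    d = make_dictionary(make_concept("C1", "beta-cyclodextrin"))
    doc = "treated with hydroxypropyl beta-cyclodextrin daily"
    raw, filtered, pre, log, kept = _pipeline_artifacts(d, doc)
    golds = [gold("d0", 13, 44, "hydroxypropyl beta-cyclodextrin", EntityClass.IUPAC)]
    assert doc[13:44] == "hydroxypropyl beta-cyclodextrin"
    table, fn_labels, fp_labels = categorize_errors(kept, golds, raw, filtered, pre, log)
    assert [lab for _, lab in fn_labels] == ["partial_match"]
    assert [lab for _, lab in fp_labels] == ["partial_match"]
    assert table == {"fn:partial_match": 1, "fp:partial_match": 1}


def test_fn_not_in_dictionary():
    d = make_dictionary(make_concept("C1", "beta-cyclodextrin"))
    doc = "caffeine was also given"
    raw, filtered, pre, log, kept = _pipeline_artifacts(d, doc)
    golds = [gold("d0", 0, 8, "caffeine", EntityClass.TRIV)]
    _, fn_labels, _ = categorize_errors(kept, golds, raw, filtered, pre, log)
    assert [lab for _, lab in fn_labels] == ["not_in_dictionary"]


def test_fn_removed_by_disambiguation(arsenic_dictionary):
    doc = "As we show, results differ"
    raw, filtered, pre, log, kept = _pipeline_artifacts(arsenic_dictionary, doc)
    golds = [gold("d0", 0, 2, "As", EntityClass.ABB)]
    _, fn_labels, _ = categorize_errors(kept, golds, raw, filtered, pre, log)
    assert [lab for _, lab in fn_labels] == ["removed_by_disambiguation"]


def test_fn_removed_by_stoplist():
    from chemlex import FilterConfig

    d = make_dictionary(make_concept("C1", "methyl group", "Me"))
    doc = "Me levels were high"
    raw, filtered, pre, log, kept = _pipeline_artifacts(
        d, doc, FilterConfig(stoplist=frozenset({"me"}))
    )
    golds = [gold("d0", 0, 2, "Me", EntityClass.ABB)]
    _, fn_labels, _ = categorize_errors(kept, golds, raw, filtered, pre, log)
    assert [lab for _, lab in fn_labels] == ["removed_by_stoplist"]


def test_fn_categories_partition_the_fn_set():
    d = make_dictionary(
        make_concept("C1", "beta-cyclodextrin"), make_concept("C2", "Arsenic", "As")
    )
    doc = "hydroxypropyl beta-cyclodextrin and caffeine; As we show"
    raw, filtered, pre, log, kept = _pipeline_artifacts(d, doc)
    golds = [
        gold("d0", 0, 31, "hydroxypropyl beta-cyclodextrin", EntityClass.IUPAC),
        gold("d0", 36, 44, "caffeine", EntityClass.TRIV),
        gold("d0", 46, 48, "As", EntityClass.ABB),
    ]
    counts = score(kept, golds)
    _, fn_labels, _ = categorize_errors(kept, golds, raw, filtered, pre, log)
    assert len(fn_labels) == counts.fn  # one label per FN, no more no less
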