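"""Cross-lingual megalemma dictionary, megatokens, merge proposals."""

import numpy as np
import pytest

from termspace.corpus import Corpus, Document
from termspace.megalemma import (
    MegalemmaDict,
    Megatoken,
    MegatokenEncoder,
    build_context_sets,
    load_embeddings,
    lookup,
    megatoken_of,
    propose_merge,
    text_to_megatokens,
)
from termspace.synthetic import parallel_documents


class TestLookup:
    @pytest.mark.parametrize(
        "form, lang, expected",
        [
            ("diseases", "en", "DISEASE"),
            ("virusnye", "ru", "VIRUS"),
            ("qwerty", "en", None),
            ("Diseases", "en", "DISEASE"),  # normalized before lookup
        ],
    )
    def test_examples(self, gen_disease_dict, form, lang, expected):
        assert lookup(form, lang, gen_disease_dict) == expected

    def test_language_keyed_reverse_index(self, gen_disease_dict):
        # the Russian transliteration is not an English form
        assert gen_disease_dict.lookup("virusnye", "en") is None

    def test_one_megalemma_per_form_per_language(self, gen_disease_dict):
        with pytest.raises(ValueError, match="already belongs"):
            gen_disease_dict.add("OTHER", [("disease", "en")])
        # same spelling in another language is allowed
        gen_disease_dict.add("OTHER", [("disease", "fr")])
        assert gen_disease_dict.lookup("disease", "fr") == "OTHER"


class TestMegatoken:
    def test_gen_disease_worked_example(self, gen_disease_dict):
        mt = megatoken_of(("genetic", "disease"), "en", gen_disease_dict)
        assert mt.labels == ("DISEASE", "GEN")  # canonical lexicographic
        assert mt.display() == "GEN + DISEASE"  # root-first rendering

    def test_order_invariance(self, gen_disease_dict):
        a = megatoken_of(("genetic", "disease"), "en", gen_disease_dict)
        b = megatoken_of(("disease", "genetic"), "en", gen_disease_dict)
        assert a == b

    def test_unmapped_member_gives_none(self, gen_disease_dict):
        assert megatoken_of(("genetic", "qwerty"), "en", gen_disease_dict) is None

    def test_permutation_invariance_beyond_pairs(self, gen_disease_dict):
        import itertools

        tokens = ("genetic", "disease", "patient")
        results = {
            megatoken_of(p, "en", gen_disease_dict)
            for p in itertools.permutations(tokens)
        }
        assert len(results) == 1

    def test_display_without_root_label_keeps_canonical_order(self):
        mt = Megatoken(("PATIENT", "DISEASE"))
        assert mt.display(root_labels=()) == "DISEASE + PATIENT"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            Megatoken(())


class TestTextToMegatokens:
    def test_adjacent_known_pair_merged(self, gen_disease_dict):
        doc = Document("d", 2019, title="", abstract="genetic disease in patients")
        seq = text_to_megatokens(doc, gen_disease_dict)
        assert seq.labels() == ["DISEASE + GEN", "PATIENT"]
        # 3 of 4 tokens mapped
        assert seq.coverage == pytest.approx(0.75)

    def test_adjacent_unknown_pair_not_merged(self, gen_disease_dict):
        doc = Document("d", 2019, title="", abstract="virus patient")
        seq = text_to_megatokens(doc, gen_disease_dict)
        # VIRUS+PATIENT is not a dictionary-known megatoken
        assert seq.labels() == ["VIRUS", "PATIENT"]

    def test_empty_text_coverage_zero(self, gen_disease_dict):
        # punctuation-only text tokenizes to nothing: empty sequence,
        # coverage defined as zero
        doc = Document("d", 2019, title="...", abstract="")
        seq = text_to_megatokens(doc, gen_disease_dict)
        assert seq.items == [] and seq.coverage == 0.0

    def test_only_unknown_words(self, gen_disease_dict):
        doc = Document("d", 2019, title="", abstract="lorem ipsum dolor")
        seq = text_to_megatokens(doc, gen_disease_dict)
        assert len(seq) == 0 and seq.coverage == 0.0

    def test_parallel_languages_identical_sequences(self, gen_disease_dict):
        docs = parallel_documents(
            ["GEN", "DISEASE", "PATIENT", "VIRUS"], gen_disease_dict, ["en", "ru"]
        )
        seq_en, seq_ru = (text_to_megatokens(d, gen_disease_dict) for d in docs)
        assert seq_en.items == seq_ru.items
        assert seq_en.coverage == seq_ru.coverage == 1.0

    def test_encoder_transformer(self, gen_disease_dict):
        docs = [Document("d", 2019, title="", abstract="genetic disease")]
        enc = MegatokenEncoder(dictionary=gen_disease_dict)
        out = enc.fit_transform(docs)
        assert out[0].labels() == ["DISEASE + GEN"]

    def test_encoder_requires_dictionary(self):
        with pytest.raises(ValueError):
            MegatokenEncoder().fit()


class TestPersistence:
    def test_roundtrip(self, gen_disease_dict, tmp_path):
        path = tmp_path / "megalemmas.tsv"
        gen_disease_dict.save(path)
        back = MegalemmaDict.load(path)
        assert back == gen_disease_dict
        assert back.megatokens == gen_disease_dict.megatokens

    def test_comments_ignored(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("# comment\nVIRUS\tvirus\ten\n")
        d = MegalemmaDict.load(path)
        assert d.lookup("virus", "en") == "VIRUS"


class TestProposeMerge:
    @pytest.fixture
    def toy_dict(self):
        d = MegalemmaDict()
        d.add("VIRUS", [("virus", "en")])
        d.add("PATIENT", [("patient", "en")])
        return d

    @pytest.fixture
    def contexts(self, toy_dict):
        corpus = Corpus([
            Document("a", 2019, title="", abstract="virus infects patient"),
            Document("b", 2019, title="", abstract="viral load in patient"),
        ])
        return build_context_sets(corpus, toy_dict, window=5)

    def test_identity_vector_with_shared_context_ranks_first(self, toy_dict, contexts):
        emb = {"virus": np.array([1.0, 0.0]), "viral": np.array([1.0, 0.0]),
               "patient": np.array([0.0, 1.0])}
        props = propose_merge("viral", "en", toy_dict, emb, contexts)
        assert props and props[0].label == "VIRUS"
        assert props[0].cosine == pytest.approx(1.0)

    def test_orthogonal_vector_yields_no_proposal(self, toy_dict, contexts):
        emb = {"virus": np.array([1.0, 0.0]), "patient": np.array([1.0, 0.0]),
               "metric": np.array([0.0, 1.0])}
        assert propose_merge("metric", "en", toy_dict, emb, contexts) == []

    def test_missing_embedding_names_word(self, toy_dict, contexts):
        with pytest.raises(KeyError, match="nosuchword"):
            propose_merge("nosuchword", "en", toy_dict, {}, contexts)

    def test_planted_cluster_structure_recovered(self):
        # two well-separated embedding clusters; each new word must be
        # proposed for (only) the megalemma planted in its cluster
        rng = np.random.default_rng(5)
        d = MegalemmaDict()
        centers = {"ALPHA": np.array([10.0, 0.0, 0.0]), "BETA": np.array([0.0, 10.0, 0.0])}
        emb = {}
        docs = []
        for label, center in centers.items():
            members = [f"{label.lower()}{i}" for i in range(3)]
            d.add(label, [(m, "en") for m in members])
            for m in members + [f"new{label.lower()}"]:
                emb[m] = center + rng.normal(scale=0.2, size=3)
            docs.append(Document(label, 2019, title="",
                                 abstract=" ".join(members + [f"new{label.lower()}"] + members)))
        contexts = build_context_sets(Corpus(docs), d, window=10)
        for label in centers:
            props = propose_merge(f"new{label.lower()}", "en", d, emb, contexts)
            assert [p.label for p in props] == [label]


def test_load_embeddings_with_and_without_header(tmp_path):
    p1 = tmp_path / "plain.vec"
    p1.write_text("virus 1.0 0.0\npatient 0.0 1.0\n")
    v = load_embeddings(p1)
    assert set(v) == {"virus", "patient"}
    np.testing.assert_allclose(v["virus"], [1.0, 0.0])
    p2 = tmp_path / "w2v.vec"
    p2.write_text("2 2\nvirus 1.0 0.0\npatient 0.0 1.0\n")
    assert set(load_embeddings(p2)) == {"virus", "patient"}
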