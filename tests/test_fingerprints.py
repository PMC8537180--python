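"""Motif extraction, consensus rules, classification, mechanism calls."""

import math

import numpy as np
import pytest

from specmap import (
    Alignment,
    SelectedPositions,
    SubgroupPartition,
    classify_sequence,
    consensus_token,
    extract_motifs,
    generate_family,
    load_fingerprint_table,
    load_specificity_table,
    mechanism_call,
    parse_motif,
)
from specmap.cma import SequenceWeights
from specmap.errors import ConfigError, DimensionError
from specmap.simulate import FamilySpec


def sel_for(columns):
    return SelectedPositions(
        positions=list(columns), columns=list(columns),
        max_score={c: 1.0 for c in columns},
        n_partners={c: 2 for c in columns},
    )


class TestConsensusToken:
    def test_pure_column_single_letter(self):
        assert consensus_token({"E": 1.0}) == "E"

    def test_even_pair_bracketed(self):
        assert consensus_token({"M": 0.5, "F": 0.5}) == "[MF]"

    def test_uniform_five_is_wildcard(self):
        assert consensus_token({r: 0.2 for r in "ACDEF"}) == "x"

    def test_dominant_with_margin(self):
        assert consensus_token({"K": 0.6, "R": 0.3, "A": 0.1}) == "K"

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            consensus_token({"K": 0.4})

    def test_zero_coverage_is_wildcard(self):
        assert consensus_token({"K": 0.0}) == "x"


class TestExtractMotifs:
    def test_invariant_position_full_information(self):
        aln = Alignment(
            ids=("a", "b", "c", "d"), rows=("KA", "KC", "KD", "KE")
        )
        part = SubgroupPartition(assignments={s: "1" for s in aln.ids})
        mots = extract_motifs(aln, part, sel_for([1]))
        assert mots[0].tokens == ["K"]
        assert mots[0].information[1] == pytest.approx(math.log2(20))

    def test_mp_like_subgroup_yields_reference_motif(self):
        # K / V / (M or F at 50:50) / N / E / S at the six positions
        rows = tuple(
            "KV" + ("M" if i % 2 else "F") + "NES" for i in range(10)
        )
        aln = Alignment(ids=tuple(f"mp{i}" for i in range(10)), rows=rows)
        part = SubgroupPartition(assignments={s: "MPs" for s in aln.ids})
        mots = extract_motifs(aln, part, sel_for([1, 2, 3, 4, 5, 6]))
        assert mots[0].consensus == "KV[MF]NES"

    def test_weighted_frequencies_match_hand_count(self):
        rows = ("KA", "KA", "RA", "KC", "RC", "KD", "KD", "RA", "KA", "RC")
        ids = tuple(f"s{i}" for i in range(10))
        aln = Alignment(ids=ids, rows=rows)
        part = SubgroupPartition(assignments={s: "g" for s in ids})
        w = np.array([2.0, 1.0, 1.0, 1.0, 1.0, 0.5, 0.5, 1.0, 1.0, 0.5])
        w = w * (10 / w.sum())
        weights = SequenceWeights(ids=ids, values=w)
        mots = extract_motifs(aln, part, sel_for([1]), weights)
        wk = w[0] + w[1] + w[3] + w[5] + w[6] + w[8]
        assert mots[0].frequencies.loc[1, "K"] == pytest.approx(wk / 10, abs=1e-12)
        assert mots[0].frequencies.loc[1].sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_coverage_position_is_wildcard(self):
        aln = Alignment(ids=("a", "b"), rows=("-K", "-R"))
        part = SubgroupPartition(assignments={"a": "1", "b": "1"})
        mots = extract_motifs(aln, part, sel_for([1, 2]))
        assert mots[0].tokens[0] == "x"


class TestClassification:
    def test_parse_motif_tokens(self):
        assert parse_motif("KV[MF]NES") == ["K", "V", "[MF]", "N", "E", "S"]
        assert parse_motif("EEAPxx") == ["E", "E", "A", "P", "x", "x"]
        with pytest.raises(ValueError):
            parse_motif("K[")

    @pytest.mark.parametrize(
        "query,expected",
        [
            ("TRIGPP", "TP"),
            ("FAITQA", "oligoNP"),
            ("EEAPWS", "KP"),
            ("DQGQDE", "T6PP"),
            ("KVFNES", "MP"),
            ("KVMNES", "MP"),
        ],
    )
    def test_worked_examples(self, query, expected):
        pred = classify_sequence(query)
        assert pred.best_label == expected
        assert pred.match_score == pytest.approx(1.0)

    def test_wildcards_excluded_from_denominator(self):
        # EEAPxx is a 4-position constraint: EEAPAA matches perfectly
        pred = classify_sequence("EEAPAA")
        assert pred.best_label == "KP" and pred.match_score == 1.0

    def test_case_insensitive(self):
        assert classify_sequence("trigpp").best_label == "TP"

    def test_below_threshold_unknown(self):
        pred = classify_sequence("WWWWWW")
        assert pred.best_label == "unknown"

    def test_tie_yields_unknown(self):
        import pandas as pd

        table = pd.DataFrame(
            {"specificity_label": ["A1", "A2"], "motif_string": ["KKKKKK", "KKKKKK"]}
        )
        assert classify_sequence("KKKKKK", table).best_label == "unknown"

    def test_all_wildcard_motif_never_wins(self):
        import pandas as pd

        table = pd.DataFrame(
            {"specificity_label": ["free", "real"],
             "motif_string": ["xxxxxx", "KKKKKK"]}
        )
        pred = classify_sequence("RRRRRR", table)
        assert "free" not in pred.per_label

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            classify_sequence("KVM")

    def test_specificity_vocabulary(self):
        df = load_specificity_table()
        assert len(df) == 10
        assert set(df["label"]) == {
            "MP", "TP", "T6PP", "KP", "NP", "GRP", "GGP", "oligoNP", "TH", "PGGHG"
        }
        # EC numbers present for every characterized specificity
        assert df["ec"].notna().all()


class TestSelfConsistency:
    @staticmethod
    def _injective_family(epsilon, seed=0):
        # 8 subgroups, 6 planted columns, distinct residue per subgroup
        planted = {c: "ACDEFGHI"[:8] for c in (3, 7, 11, 15, 19, 23)}
        spec = FamilySpec(
            n_subgroups=8, seqs_per_subgroup=12, n_columns=30,
            planted=planted, epsilon=epsilon, gap_rate=0.0, seed=seed,
        )
        return spec, generate_family(spec)

    def test_planted_members_recover_their_subgroup(self):
        import pandas as pd

        spec, (aln, _, part, truth) = self._injective_family(epsilon=0.0)
        sel = sel_for(truth["planted_columns"])
        mots = extract_motifs(aln, part, sel)
        table = pd.DataFrame(
            {"specificity_label": [m.subgroup_id for m in mots],
             "motif_string": [m.consensus for m in mots]}
        )
        hits = 0
        total = 0
        for sid, row in aln.records():
            query = "".join(row[c - 1] for c in sel.columns)
            pred = classify_sequence(query, table)
            total += 1
            hits += pred.best_label == part.assignments[sid]
        assert hits == total  # 100% at epsilon = 0

    def test_shuffled_labels_destroy_consistency(self):
        import pandas as pd

        spec, (aln, _, part, truth) = self._injective_family(epsilon=0.0)
        rng = np.random.default_rng(4)
        ids = list(part.assignments)
        labels = [part.assignments[s] for s in ids]
        rng.shuffle(labels)
        shuffled = SubgroupPartition(assignments=dict(zip(ids, labels)))
        sel = sel_for(truth["planted_columns"])
        mots = extract_motifs(aln, shuffled, sel)
        table = pd.DataFrame(
            {"specificity_label": [m.subgroup_id for m in mots],
             "motif_string": [m.consensus for m in mots]}
        )
        hits = sum(
            classify_sequence(
                "".join(row[c - 1] for c in sel.columns), table
            ).best_label == shuffled.assignments[sid]
            for sid, row in aln.records()
        )
        # chance level is ~1/8; allow generous slack but far below 100%
        assert hits / aln.n_sequences < 0.5


class TestMechanismCall:
    POSITIONS = [2, 4]
    RESIDUES = {2: {"R", "K"}, 4: {"T"}}

    def test_all_positions_match_phosphorylase(self):
        assert mechanism_call("ARCTA", self.POSITIONS, self.RESIDUES) == "phosphorylase"

    def test_one_deviation_hydrolase(self):
        assert mechanism_call("ARCVA", self.POSITIONS, self.RESIDUES) == "hydrolase"

    def test_gap_undetermined(self):
        assert mechanism_call("A-CTA", self.POSITIONS, self.RESIDUES) == "undetermined"

    def test_unconfigured_raises(self):
        with pytest.raises(ConfigError):
            mechanism_call("ARCTA", [], {})


def test_packaged_fingerprint_table_contents():
    df = load_fingerprint_table()
    motifs = dict(zip(df["specificity_label"], df["motif_string"]))
    assert motifs["MP"] == "KV[MF]NES"
    assert motifs["KP"] == "EEAPxx"
    assert motifs["TP"] == "TRIGPP"
    assert motifs["oligoNP"] == "FAITQA"
    assert motifs["T6PP"] == "DQGQDE"
    assert motifs["subgroup_7"] == "SVSWRQ"
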