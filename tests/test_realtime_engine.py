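import numpy as np
import pandas as pd
import pytest

import squigselect as sq
from squigselect.realtime_engine import (DecisionRecord, OracleClassifier,
                                         ReadState, RunConfig, decide,
                                         decisions_to_frame, playback_run,
                                         step, write_decisions, write_log)
from squigselect.preprocess import SAMPLE_RATE
from conftest import scripted_read


class ScriptedModel:
    """Returns a fixed probability per read (or a sequence popped per
    assessment) — for protocol tests without a trained network."""

    def __init__(self, probs):
        self.probs = dict(probs)

    def predict_for_read(self, window, read_id):
        p = self.probs[read_id]
        if isinstance(p, list):
            return p.pop(0)
        return p


def make_raw_read(read_id, channel, cls="target", tx_s=6.0, seed=0):
    signal, a_end, p_end = scripted_read(adapter_s=1.0, polya_s=1.0,
                                         tx_s=tx_s, seed=seed)
    truth = sq.synthetic_data.ReadTruth(cls, f"T_{cls}", f"G_{cls}",
                                        "mRNA" if cls == "target" else "lncRNA",
                                        a_end, p_end, signal.size)
    return sq.RawRead(read_id, channel, signal, SAMPLE_RATE, truth)


class TestDecide:
    @pytest.mark.parametrize("probs,mode,expected", [
        ({"a": 0.95}, "deplete", "reject"),
        ({"a": 0.05}, "deplete", "accept"),
        ({"a": 0.3, "b": 0.95}, "deplete", "reject"),  # any confident target
        ({"a": 0.3, "b": 0.05}, "deplete", "wait"),    # accept needs all < 1-T
        ({"a": 0.9}, "deplete", "wait"),               # exactly T is not enough
        ({"a": 0.95}, "enrich", "accept"),
        ({"a": 0.05}, "enrich", "reject"),
        ({"a": 0.5}, "enrich", "wait"),
    ])
    def test_rules(self, probs, mode, expected):
        assert decide(probs, mode, 0.9) == expected

    def test_empty_probabilities_rejected(self):
        with pytest.raises(ValueError):
            decide({}, "deplete", 0.9)

    def test_enrich_multi_target_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(mode="enrich", targets=("a", "b"))

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            RunConfig(threshold=0.5)


class TestStep:
    def _stream(self, probs, tx_s=6.0):
        read = make_raw_read("r0", 2, tx_s=tx_s)
        config = RunConfig(mode="deplete", targets=("target",))
        models = {"target": ScriptedModel({"r0": probs})}
        state = ReadState("r0", 2)
        commands = []
        chunk = config.chunk_samples
        for i in range(0, read.signal.size, chunk):
            state, cmd = step(state, read.signal[i:i + chunk], models, config)
            commands.append(cmd)
            if state.status not in ("streaming",):
                break
        return state, commands

    def test_confident_first_assessment_rejects(self):
        state, commands = self._stream(0.97)
        assert state.status == "rejected"
        assert commands[-1] == "reject"
        assert state.last_assessed_seconds == 2
        assert state.rejects_sent == 1

    def test_wait_then_reject_at_four_seconds(self):
        state, commands = self._stream([0.6, 0.8, 0.95])
        assert state.status == "rejected"
        assert state.last_assessed_seconds == 4

    def test_never_confident_completes_unaffected(self):
        state, commands = self._stream([0.6, 0.6, 0.6])
        assert state.status == "undecided_complete"
        assert all(c is None for c in commands)
        assert state.last_assessed_seconds == 4  # final attempt on first 4 s

    def test_chunks_after_terminal_ignored(self):
        state, _ = self._stream(0.97)
        seen = state.samples_seen
        state2, cmd = step(state, np.zeros(100), {}, RunConfig())
        assert cmd is None and state2.samples_seen == seen


class TestPlayback:
    def _reads(self, n=20, target_frac=0.5, seed=0):
        rng = np.random.default_rng(seed)
        reads = []
        for i in range(n):
            cls = "target" if rng.random() < target_frac else "nontarget"
            reads.append(make_raw_read(f"r{i}", channel=int(rng.integers(1, 9)),
                                       cls=cls, tx_s=float(rng.uniform(4.5, 7)),
                                       seed=i))
        return reads

    def _oracle(self, reads):
        return {"target": OracleClassifier(
            "target", {r.read_id: r.truth.class_label for r in reads})}

    def test_control_reads_untouched(self):
        reads = [make_raw_read(f"r{i}", channel=3, seed=i) for i in range(5)]
        res = playback_run(reads, self._oracle(reads), RunConfig())
        assert (res.table.delivered_samples == res.table.input_samples).all()
        assert (res.table.status == "control_complete").all()
        assert res.decisions == []

    def test_perfect_oracle_decisions(self):
        reads = self._reads(30)
        res = playback_run(reads, self._oracle(reads), RunConfig())
        t = res.table
        trt = t[t.condition == "treatment"]
        assert (trt[trt["class"] == "target"].status == "rejected").all()
        assert (trt[trt["class"] == "target"].delivered_samples
                < trt[trt["class"] == "target"].input_samples).all()
        assert (trt[trt["class"] == "nontarget"].status == "accepted").all()
        assert (trt[trt["class"] == "nontarget"].delivered_samples
                == trt[trt["class"] == "nontarget"].input_samples).all()
        assert len(res.decisions) == len(trt)

    def test_conservation_and_single_reject(self):
        reads = self._reads(40, seed=3)
        res = playback_run(reads, self._oracle(reads), RunConfig())
        assert sorted(res.table.read_id) == sorted(r.read_id for r in reads)
        assert set(res.table.status) <= {"rejected", "accepted",
                                         "undecided_complete", "control_complete"}
        assert res.table.rejects_sent.max() <= 1

    def test_enrich_deplete_symmetry(self):
        reads = self._reads(30, seed=4)
        models = self._oracle(reads)
        dep = playback_run(reads, models, RunConfig(mode="deplete",
                                                    targets=("target",)))
        enr = playback_run(reads, models, RunConfig(mode="enrich",
                                                    targets=("target",)))
        d = dep.table.set_index("read_id").status
        e = enr.table.set_index("read_id").status
        mirror = {"rejected": "accepted", "accepted": "rejected",
                  "undecided_complete": "undecided_complete",
                  "control_complete": "control_complete"}
        assert all(e[rid] == mirror[d[rid]] for rid in d.index)

    def test_reject_latency_bounds_delivered_length(self):
        reads = self._reads(20, target_frac=1.0, seed=5)
        config = RunConfig(eject_latency_chunks=1)
        res = playback_run(reads, self._oracle(reads), config)
        trt = res.table[res.table.status == "rejected"]
        expected = (trt.decision_batch + 1 + config.eject_latency_chunks) \
            * config.chunk_samples
        assert (trt.delivered_samples <= np.minimum(expected, trt.input_samples)).all()

    def test_duration_limits_assessment(self):
        reads = self._reads(10, seed=6)
        res = playback_run(reads, self._oracle(reads),
                           RunConfig(duration_seconds=1.0))
        assert res.decisions == []
        assert (res.table.delivered_samples == res.table.input_samples).all()

    def test_failed_rejects_complete_but_count_once(self):
        reads = self._reads(20, target_frac=1.0, seed=7)
        res = playback_run(reads, self._oracle(reads),
                           RunConfig(reject_failure_prob=1.0))
        trt = res.table[res.table.condition == "treatment"]
        assert (trt.status == "reject_failed").all()
        assert (trt.delivered_samples == trt.input_samples).all()
        assert trt.rejects_sent.max() == 1

    def test_no_read_assessed_beyond_four_seconds(self):
        reads = self._reads(30, seed=8)
        res = playback_run(reads, self._oracle(reads), RunConfig())
        assert res.table.samples_assessed.max() <= 4 * SAMPLE_RATE


class TestOutputs:
    def test_empty_run_header_only(self, tmp_path):
        config = RunConfig(targets=("mRNA", "mtRNA"))
        path = tmp_path / "decisions.csv"
        write_decisions([], config, path)
        df = pd.read_csv(path)
        assert len(df) == 0
        assert list(df.columns) == ["read_id", "batch", "channel",
                                    "samples_assessed", "prob_mRNA",
                                    "prob_mtRNA", "threshold", "decision"]

    def test_log_tallies_match_decisions(self, tmp_path):
        reads = [make_raw_read(f"r{i}", channel=2, cls=c, seed=i)
                 for i, c in enumerate(["target", "nontarget"] * 5)]
        models = {"target": OracleClassifier(
            "target", {r.read_id: r.truth.class_label for r in reads})}
        res = playback_run(reads, models, RunConfig())
        log_path = tmp_path / "run.log"
        write_log(res, log_path)
        text = log_path.read_text()
        counts = res.decisions_frame().decision.value_counts()
        for name, n in counts.items():
            assert f"decisions[{name}]: {n}" in text
        assert f"assessed reads: {len(res.decisions)}" in text

    def test_row_count_equals_assessed_reads(self, tmp_path):
        reads = [make_raw_read(f"r{i}", channel=2, seed=i) for i in range(6)]
        models = {"target": OracleClassifier(
            "target", {r.read_id: "target" for r in reads})}
        res = playback_run(reads, models, RunConfig())
        path = tmp_path / "d.csv"
        write_decisions(res.decisions, res.config, path)
        assert len(pd.read_csv(path)) == len(res.decisions) == 6

    def test_decision_record_invariants(self):
        with pytest.raises(ValueError):
            DecisionRecord("r", 0, 1, 100, {"a": 1.5}, 0.9, "reject")
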