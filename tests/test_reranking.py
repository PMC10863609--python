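"""Answer parsing (mapping f), built-in backends, HTTP backend."""

from __future__ import annotations

import http.server
import json
import threading

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bkf.models import AlignmentPair, AlignmentSet, Hierarchy, Term
from bkf.prompting import assemble_prompt, make_pseudo_demonstration
from bkf.reranking import (
    BackendError,
    HTTPBackend,
    NoopBackend,
    OracleBackend,
    TokenOverlapBackend,
    builtin_backends,
    parse_answer,
    rerank,
)
from bkf.retrieval import CandidateList, ExpansionStrategy

NAMES = {
    "t1": "allergic disease",
    "t2": "immune system disease",
    "t3": "immune system cancer",
}


def _cands(ids=("t1", "t2", "t3"), entity_id="e1"):
    return CandidateList(entity_id=entity_id,
                         ranked=tuple((t, float(10 - i)) for i, t in enumerate(ids)),
                         strategy=ExpansionStrategy())


class TestParseAnswer:
    def test_reorders_matched_then_backfills(self):
        result = parse_answer("Answer: immune system disease; allergic disease",
                              _cands(), NAMES.__getitem__)
        assert list(result.ranked_terms) == ["t2", "t1", "t3"]
        assert result.parse_report == {"matched": 2, "dropped": 0, "backfilled": 1}

    def test_identity_permutation(self):
        completion = "Answer: " + "; ".join(NAMES[t] for t in ("t1", "t2", "t3"))
        result = parse_answer(completion, _cands(), NAMES.__getitem__)
        assert list(result.ranked_terms) == ["t1", "t2", "t3"]

    def test_garbage_falls_back_to_retrieval_order(self):
        result = parse_answer("garbage text", _cands(), NAMES.__getitem__)
        assert list(result.ranked_terms) == ["t1", "t2", "t3"]
        assert result.parse_report["matched"] == 0
        assert result.parse_report["backfilled"] == 3

    def test_normalization_and_duplicates(self):
        completion = "Answer:  IMMUNE  system disease ;immune system disease; unknown name"
        result = parse_answer(completion, _cands(), NAMES.__getitem__)
        assert result.ranked_terms[0] == "t2"
        assert result.parse_report["dropped"] == 1

    def test_text_before_answer_marker_ignored(self):
        completion = "thinking...\nAnswer: allergic disease"
        result = parse_answer(completion, _cands(), NAMES.__getitem__)
        assert result.ranked_terms[0] == "t1"

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.text(max_size=200))
    def test_always_a_permutation(self, completion):
        result = parse_answer(completion, _cands(), NAMES.__getitem__)
        assert sorted(result.ranked_terms) == ["t1", "t2", "t3"]


class TestBuiltinBackends:
    def _world(self):
        terms = [Term(id=t, name=n) for t, n in NAMES.items()] + [
            Term(id="r", name="disease of anatomical entity")]
        h = Hierarchy(terms, [("t1", "r"), ("t2", "r"), ("t3", "r")])
        gold = AlignmentSet([AlignmentPair("e1", "t2")])
        return h, gold

    def _prompt(self, h, cand, query="immune suppression"):
        return assemble_prompt("T.", [make_pseudo_demonstration()], cand, query, h)

    def test_token_overlap_exact_match_first(self):
        be = TokenOverlapBackend()
        prompt = ("Query: epidemic typhus\n"
                  "Choices: typhus; epidemic typhus; scrub typhus\n"
                  "Answer:")
        assert be.complete(prompt) == "Answer: epidemic typhus; typhus; scrub typhus"

    def test_noop_echoes_choices(self):
        h, _ = self._world()
        prompt = self._prompt(h, _cands())
        completion = NoopBackend().complete(prompt.rendered)
        assert completion == "Answer: " + "; ".join(NAMES[t] for t in ("t1", "t2", "t3"))

    def test_oracle_puts_gold_first(self):
        h, gold = self._world()
        cand = _cands()
        result = rerank(self._prompt(h, cand), cand, OracleBackend(gold, h), h)
        assert result.ranked_terms[0] == "t2"

    def test_oracle_unknown_entity_falls_back_to_noop(self, caplog):
        h, gold = self._world()
        cand = _cands(entity_id="eX")
        result = rerank(self._prompt(h, cand), cand, OracleBackend(gold, h), h)
        assert list(result.ranked_terms) == ["t1", "t2", "t3"]

    def test_deterministic_backend_repeats(self):
        h, gold = self._world()
        cand = _cands()
        be = TokenOverlapBackend()
        assert rerank(self._prompt(h, cand), cand, be, h) == \
               rerank(self._prompt(h, cand), cand, be, h)

    def test_builtin_backends_dict(self):
        h, gold = self._world()
        assert set(builtin_backends()) == {"noop", "token_overlap"}
        assert set(builtin_backends(gold=gold, h=h)) == {"noop", "token_overlap", "oracle"}
        with pytest.raises(ValueError):
            builtin_backends(gold=gold)


class _Handler(http.server.BaseHTTPRequestHandler):
    """Echoes the last Choices line; optionally fails with 500 first."""

    fail_all = False
    seen_payloads: list[dict] = []

    def do_POST(self):  # noqa: N802
        body = json.loads(self.rfile.read(int(self.headers["Content-Length"])))
        type(self).seen_payloads.append(body)
        if type(self).fail_all:
            self.send_response(500)
            self.end_headers()
            return
        choices = [ln for ln in body["prompt"].splitlines()
                   if ln.startswith("Choices: ")][-1][len("Choices: "):]
        payload = json.dumps({"completion": "Answer: " + choices}).encode()
        self.send_response(200)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(payload)))
        self.end_headers()
        self.wfile.write(payload)

    def log_message(self, *args):  # silence
        pass


@pytest.fixture()
def mock_server():
    server = http.server.HTTPServer(("127.0.0.1", 0), _Handler)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    _Handler.fail_all = False
    _Handler.seen_payloads = []
    yield f"http://127.0.0.1:{server.server_port}"
    server.shutdown()


class TestHTTPBackend:
    def test_echo_server_identity_permutation(self, mock_server):
        be = HTTPBackend(mock_server, retries=2, backoff=0.01)
        prompt = "Query: q\nChoices: allergic disease; immune system disease\nAnswer:"
        cand = _cands(ids=("t1", "t2"))
        completion = be.complete(prompt)
        result = parse_answer(completion, cand, NAMES.__getitem__)
        assert list(result.ranked_terms) == ["t1", "t2"]

    def test_temperature_zero_by_default(self, mock_server):
        be = HTTPBackend(mock_server, retries=1)
        be.complete("Query: q\nChoices: x\nAnswer:")
        assert _Handler.seen_payloads[-1]["temperature"] == 0

    def test_retries_then_structured_failure(self, mock_server):
        _Handler.fail_all = True
        be = HTTPBackend(mock_server, retries=3, backoff=0.01)
        with pytest.raises(BackendError, match="after 3 attempts"):
            be.complete("Query: q\nChoices: x\nAnswer:", entity_id="e9")
        assert len(_Handler.seen_payloads) == 3
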