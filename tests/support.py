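"""Shared assertions for cross-validation reports."""

import pytest


def check_report_invariants(report):
    """No-leakage and exact metric algebra, from the provenance log."""
    for fold in report.provenance["folds"]:
        assert not (set(fold["train_ids"]) & set(fold["val_ids"])), \
            "a model was evaluated on subjects it trained on"
        c = fold["confusion"]
        n = sum(c.values())
        m = fold["metrics"]
        assert m["accuracy"] * n == pytest.approx(c["tp"] + c["tn"])
        if c["tp"] + c["fn"]:
            assert m["sensitivity"] == pytest.approx(c["tp"] / (c["tp"] + c["fn"]))
        if c["tn"] + c["fp"]:
            assert m["specificity"] == pytest.approx(c["tn"] / (c["tn"] + c["fp"]))
    for rep in report.per_repeat:
        n = rep["tp"] + rep["fp"] + rep["tn"] + rep["fn"]
        assert rep["accuracy"] * n == pytest.approx(rep["tp"] + rep["tn"])
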