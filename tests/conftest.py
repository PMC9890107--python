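import numpy as np
import pandas as pd
import pytest

from psiseq.trial_data import CANONICAL_COLUMNS, TrialTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_table(rows: list[dict]) -> TrialTable:
    """Build a TrialTable from sparse row dicts, filling sensible defaults."""
    records = []
    for i, row in enumerate(rows):
        guessed = row.get("guessed_side", "left")
        success = row.get("success")
        target = row.get("target_side")
        if target is None:
            if success is None:
                success = True
            target = guessed if success else ("right" if guessed == "left" else "left")
        order = row.get("deposit_order", i)
        rec = {
            "session_id": row.get("session_id", "s0"),
            "participant_id": row.get("participant_id", row.get("session_id", "s0")),
            "lab_id": row.get("lab_id", "lab0"),
            "experimenter_id": row.get("experimenter_id", "e0"),
            "trial_index": row.get("trial_index", i + 1),
            "trial_type": row.get("trial_type", "erotic"),
            "guessed_side": guessed,
            "target_side": target,
            "success": guessed == target,
            "deposit_order": order,
            "timestamp_hash": row.get("timestamp_hash", f"h{order:04d}"),
            "experimenter_asgs": row.get("experimenter_asgs", pd.NA),
            "sitepi_asgs": row.get("sitepi_asgs", pd.NA),
            "esp_belief": row.get("esp_belief", pd.NA),
            "sensation_seeking": row.get("sensation_seeking", pd.NA),
        }
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=list(CANONICAL_COLUMNS))
    return TrialTable(df=df)


def session_rows(
    session: str,
    successes: list[bool],
    experimenter: str = "e0",
    trial_type: str = "erotic",
    start_order: int = 0,
):
    """Rows of one session with given per-trial success flags."""
    return [
        {
            "session_id": session,
            "participant_id": session,
            "experimenter_id": experimenter,
            "trial_index": j + 1,
            "trial_type": trial_type,
            "guessed_side": "left",
            "success": s,
            "target_side": "left" if s else "right",
            "deposit_order": start_order + j,
        }
        for j, s in enumerate(successes)
    ]


@pytest.fixture
def three_session_table():
    """One complete session (18 erotic), one terminated after 7 erotic trials,
    one by a system-test experimenter; interleaved non-erotic trials."""
    rows = []
    # complete session, alternating successes: 9/18
    rows += session_rows("sA", [i % 2 == 0 for i in range(18)], start_order=0)
    rows += session_rows("sA", [True] * 3, trial_type="nonerotic", start_order=18)
    # terminated session: 7 erotic trials, 4 successes
    rows += session_rows("sB", [True, True, False, True, False, False, True], start_order=21)
    # test-account session
    rows += session_rows("sT", [True] * 18, experimenter="tester", start_order=28)
    return make_table(rows)
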