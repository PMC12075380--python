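"""Stimulation-protocol arithmetic (session labels only; no hardware).

The study design delivers high-frequency rTMS in fixed trains: pulses
per session = train frequency x train duration x number of trains, with
trains separated by a fixed inter-train interval. These helpers exist so
the protocol numbers used for the pre/post session labels are checkable.
"""

from __future__ import annotations

__all__ = ["rtms_session"]


def rtms_session(
    freq_hz: float = 10.0,
    train_s: float = 10.0,
    intertrain_s: float = 20.0,
    session_s: float = 900.0,
) -> dict:
    """Pulse and train counts for one rTMS session.

    A train cycle lasts train_s + intertrain_s; the number of complete
    trains fitting a session is session_s // cycle. Defaults describe a
    10 Hz, 10-s-train, 20-s-interval, ~15-minute session.
    """
    if min(freq_hz, train_s, intertrain_s, session_s) <= 0:
        raise ValueError("all protocol durations and rates must be positive")
    cycle = train_s + intertrain_s
    n_trains = int(session_s // cycle)
    pulses_per_train = int(round(freq_hz * train_s))
    return {
        "n_trains": n_trains,
        "pulses_per_train": pulses_per_train,
        "total_pulses": n_trains * pulses_per_train,
        "active_s": n_trains * train_s,
        "session_s": n_trains * cycle,
    }
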