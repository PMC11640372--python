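"""Replay the bedside warning gauge over a session, window by window.

Each gauge side is the window's max excursion area divided by the saturation
constant 6000 bpm*s (a 20 bpm deviation sustained 5 min), capped at 100%.
The tier comes from the worse side: <10% STABLE, <46% NORMAL, <83% ELEVATED,
otherwise WARNING. An IDH session typically walks up the tiers and ends in
WARNING; a normal session stays below 46%.
"""

from dialysentinel import generate_case, idh_profile, normal_profile, render_gauge, track_session

for profile, seed in ((normal_profile(), 7), (idh_profile(), 7)):
    case = generate_case(profile, seed=seed)
    print(f"\n=== {case.label.value} session ===")
    for state in track_session(case.series):
        print(render_gauge(state))
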