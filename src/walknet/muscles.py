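"""Canonical muscle labels for the 26-channel bilateral EMG montage."""

MUSCLE_NAMES = [
    ("Tibialis anterior", "TA"),
    ("Gastrocnemius medialis", "GM"),
    ("Tensor fascia latae", "TFL"),
    ("Rectus femoris", "RF"),
    ("Vastus medialis", "VM"),
    ("Adductor longus", "AL"),
    ("Biceps femoris", "BF"),
    ("Gluteus maximus", "GMA"),
    ("Erector spinae", "ES"),
    ("Latissimus dorsi", "LD"),
    ("Trapezius", "TZ"),
    ("Deltoid", "D"),
    ("Triceps brachii", "TRB"),
]

#: 26 channel labels: 13 bilateral muscles, right then left side.
MUSCLES = [f"{abbr}_{side}" for side in ("R", "L") for _, abbr in MUSCLE_NAMES]

N_MUSCLES = len(MUSCLES)


def pair_index(n: int = N_MUSCLES) -> list[tuple[int, int]]:
    """All unordered channel pairs (i < j), lexicographic. 26 -> 325 pairs."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]
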