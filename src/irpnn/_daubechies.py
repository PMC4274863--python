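"""Daubechies analysis low-pass filter coefficients, orders 1-10.

Derived once by spectral factorization of the Daubechies polynomial
(minimal-phase root selection) and frozen as literals so the filter bank
is bit-identical across platforms.  ``DB_LO_D[N]`` has length ``2 N`` and
sums to sqrt(2); high-pass and reconstruction filters are derived from it
by the quadrature-mirror relations in :mod:`irpnn.dwt`.
"""

DB_LO_D = {
    1: (
        0.7071067811865475,
        0.7071067811865475,
    ),
    2: (
        -0.12940952255126045,
        0.22414386804201333,
        0.836516303737808,
        0.4829629131445342,
    ),
    3: (
        0.03522629188570956,
        -0.08544127388202662,
        -0.1350110200102546,
        0.4598775021184915,
        0.8068915093110924,
        0.3326705529500826,
    ),
    4: (
        -0.010597401785069018,
        0.032883011666885176,
        0.030841381835560632,
        -0.18703481171909309,
        -0.02798376941685959,
        0.630880767929859,
        0.7148465705529156,
        0.23037781330889645,
    ),
    5: (
        0.0033357252854737704,
        -0.012580751999081994,
        -0.006241490212798271,
        0.0775714938400457,
        -0.03224486958463847,
        -0.24229488706638203,
        0.13842814590132088,
        0.724308528437773,
        0.6038292697971896,
        0.16010239797419293,
    ),
    6: (
        -0.0010773010853084794,
        0.0047772575109455056,
        0.0005538422011615001,
        -0.03158203931748598,
        0.027522865530305606,
        0.09750160558732306,
        -0.12976686756726188,
        -0.22626469396543933,
        0.315250351709198,
        0.751133908021095,
        0.49462389039845295,
        0.1115407433501094,
    ),
    7: (
        0.0003537137999745206,
        -0.0018016407040474935,
        0.0004295779729213669,
        0.012550998556099856,
        -0.016574541630666902,
        -0.03802993693501441,
        0.08061260915108304,
        0.07130921926683047,
        -0.22403618499387518,
        -0.14390600392856523,
        0.46978228740519296,
        0.7291320908462354,
        0.39653931948191745,
        0.07785205408500923,
    ),
    8: (
        -0.00011747678412476935,
        0.0006754494064505685,
        -0.0003917403733769473,
        -0.004870352993451561,
        0.008746094047405749,
        0.013981027917398262,
        -0.04408825393079458,
        -0.01736930100180785,
        0.12874742662047872,
        0.0004724845739130801,
        -0.28401554296154635,
        -0.015829105256348515,
        0.5853546836542065,
        0.6756307362972891,
        0.3128715909142996,
        0.054415842243103946,
    ),
    9: (
        3.9347320316271636e-05,
        -0.0002519631889427105,
        0.0002303857635231962,
        0.0018476468830562287,
        -0.004281503682463433,
        -0.004723204757751389,
        0.022361662123678974,
        0.000250947114831909,
        -0.06763282906133072,
        0.03072568147933388,
        0.14854074933810588,
        -0.09684078322297601,
        -0.2932737832791743,
        0.1331973858250076,
        0.6572880780513,
        0.6048231236901112,
        0.24383467461259023,
        0.03807794736387834,
    ),
    10: (
        -1.3264202894521241e-05,
        9.35886703200696e-05,
        -0.00011646685512928553,
        -0.0006858566949597117,
        0.0019924052951850566,
        0.0013953517470529,
        -0.010733175483330538,
        0.0036065535669560058,
        0.03321267405934137,
        -0.029457536821876858,
        -0.07139414716639458,
        0.09305736460356871,
        0.12736934033579547,
        -0.19594627437737813,
        -0.2498464243273151,
        0.28117234366057847,
        0.6884590394536033,
        0.5272011889317256,
        0.18817680007769153,
        0.026670057900555547,
    ),
}
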