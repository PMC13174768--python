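"""Embedded photon-interaction and positron-stopping data.

Linear attenuation coefficients (cm^-1) per interaction channel on a
coarse 0.05-3 MeV grid for six tissue-relevant materials, plus positron
CSDA-range tables (g/cm^2) and radiation lengths used for multiple
scattering.  Compton values follow the Klein-Nishina cross section times
electron density; pair production is anchored to standard water values
and scaled across materials by the Z(Z+1)/A composition factor;
photoelectric follows an effective-Z power law (negligible above 1 MeV).
"""

import numpy as np

ENERGY_GRID_MEV = np.array(
    [0.05, 0.08, 0.1, 0.15, 0.2, 0.3, 0.5, 0.662, 0.8, 1, 1.022, 1.25, 1.5, 2, 2.617, 3])

PAIR_THRESHOLD_MEV = 1.022

DENSITY_G_CM3 = {
    'water': 1.0,
    'adipose': 0.95,
    'lung': 0.26,
    'brain': 1.04,
    'bone': 1.92,
    'air': 0.001205,
}

# per-material linear attenuation coefficients, cm^-1, one value per
# ENERGY_GRID_MEV entry
ATTENUATION_CM1 = {
    'water': {
        'photoelectric': np.array([
            2.250000e-02, 5.493164e-03, 2.812500e-03, 8.333333e-04,
            3.515625e-04, 1.041667e-04, 2.250000e-05, 9.694347e-06,
            5.493164e-06, 2.812500e-06, 2.634753e-06, 1.440000e-06,
            8.333333e-07, 3.515625e-07, 1.569211e-07, 1.041667e-07,
        ]),
        'compton': np.array([
            1.877021e-01, 1.729196e-01, 1.647173e-01, 1.482897e-01,
            1.358801e-01, 1.181523e-01, 9.666333e-02, 8.562332e-02,
            7.854300e-02, 7.060316e-02, 6.985295e-02, 6.311908e-02,
            5.735501e-02, 4.892530e-02, 4.180489e-02, 3.847302e-02,
        ]),
        'pair': np.array([
            0.000000e+00, 0.000000e+00, 0.000000e+00, 0.000000e+00,
            0.000000e+00, 0.000000e+00, 0.000000e+00, 0.000000e+00,
            0.000000e+00, 0.000000e+00, 0.000000e+00, 8.000000e-06,
            6.000000e-05, 3.930000e-04, 8.050000e-04, 1.135000e-03,
        ]),
    },
    'adipose': {
        'photoelectric': np.array([
            1.261264e-02, 3.079257e-03, 1.576580e-03, 4.671348e-04,
            1.970725e-04, 5.839185e-05, 1.261264e-05, 5.434280e-06,
            3.079257e-06, 1.576580e-06, 1.476941e-06, 8.072089e-07,
            4.671348e-07, 1.970725e-07, 8.796397e-08, 5.839185e-08,
        ]),
        'compton': np.array([
            1.785405e-01, 1.644795e-01, 1.566776e-01, 1.410518e-01,
            1.292479e-01, 1.123854e-01, 9.194526e-02, 8.144411e-02,
            7.470938e-02, 6.715708e-02, 6.644348e-02, 6.003829e-02,
            5.455556e-02, 4.653729e-02, 3.976442e-02, 3.659519e-02,
        ]),
        'pair': np.array([
            0.000000e+00, 0.000000e+00, 0.000000e+00, 0.000000e+00,
            0.000000e+00, 0.000000e+00, 0.000000e+00, 0.000000e+00,
            0.000000e+00, 0.000000e+00, 0.000000e+00, 6.519954e-06,
            4.889966e-05, 3.202928e-04, 6.560704e-04, 9.250185e-04,
        ]),
    },
    'lung': {
        'photoelectric': np.array([
            6.280626e-03, 1.533356e-03, 7.850782e-04, 2.326158e-04,
            9.813478e-05, 2.907697e-05, 6.280626e-06, 2.706070e-06,
            1.533356e-06, 7.850782e-07, 7.354620e-07, 4.019600e-07,
            2.326158e-07, 9.813478e-08, 4.380279e-08, 2.907697e-08,
        ]),
        'compton': np.array([
            4.839757e-02, 4.458602e-02, 4.247112e-02, 3.823537e-02,
            3.503566e-02, 3.046468e-02, 2.492391e-02, 2.207733e-02,
            2.025172e-02, 1.820449e-02, 1.801105e-02, 1.627478e-02,
            1.478856e-02, 1.261502e-02, 1.077907e-02, 9.919979e-03,
        ]),
        'pair': np.array([
            0.000000e+00, 0.000000e+00, 0.000000e+00, 0.000000e+00,
            0.000000e+00, 0.000000e+00, 0.000000e+00, 0.000000e+00,
            0.000000e+00, 0.000000e+00, 0.000000e+00, 2.052991e-06,
            1.539743e-05, 1.008532e-04, 2.065822e-04, 2.912681e-04,
        ]),
    },
    'brain': {
        'photoelectric': np.array([
            2.512306e-02, 6.133560e-03, 3.140383e-03, 9.304837e-04,
            3.925478e-04, 1.163105e-04, 2.512306e-05, 1.082452e-05,
            6.133560e-06, 3.140383e-06, 2.941913e-06, 1.607876e-06,
            9.304837e-07, 3.925478e-07, 1.752150e-07, 1.163105e-07,
        ]),
        'compton': np.array([
            1.942608e-01, 1.789617e-01, 1.704729e-01, 1.534712e-01,
            1.406280e-01, 1.222808e-01, 1.000409e-01, 8.861514e-02,
            8.128743e-02, 7.307016e-02, 7.229373e-02, 6.532457e-02,
            5.935909e-02, 5.063483e-02, 4.326562e-02, 3.981734e-02,
        ]),
        'pair': np.array([
            0.000000e+00, 0.000000e+00, 0.000000e+00, 0.000000e+00,
            0.000000e+00, 0.000000e+00, 0.000000e+00, 0.000000e+00,
            0.000000e+00, 0.000000e+00, 0.000000e+00, 8.137117e-06,
            6.102838e-05, 3.997359e-04, 8.187974e-04, 1.154454e-03,
        ]),
    },
    'bone': {
        'photoelectric': np.array([
            3.697560e-01, 9.027247e-02, 4.621951e-02, 1.369467e-02,
            5.777438e-03, 1.711834e-03, 3.697560e-04, 1.593130e-04,
            9.027247e-05, 4.621951e-05, 4.329848e-05, 2.366439e-05,
            1.369467e-05, 5.777438e-06, 2.578779e-06, 1.711834e-06,
        ]),
        'compton': np.array([
            3.342218e-01, 3.079002e-01, 2.932952e-01, 2.640442e-01,
            2.419477e-01, 2.103817e-01, 1.721184e-01, 1.524606e-01,
            1.398534e-01, 1.257158e-01, 1.243800e-01, 1.123897e-01,
            1.021262e-01, 8.711624e-02, 7.443766e-02, 6.850495e-02,
        ]),
        'pair': np.array([
            0.000000e+00, 0.000000e+00, 0.000000e+00, 0.000000e+00,
            0.000000e+00, 0.000000e+00, 0.000000e+00, 0.000000e+00,
            0.000000e+00, 0.000000e+00, 0.000000e+00, 2.160890e-05,
            1.620667e-04, 1.061537e-03, 2.174395e-03, 3.065762e-03,
        ]),
    },
    'air': {
        'photoelectric': np.array([
            2.794954e-05, 6.823618e-06, 3.493692e-06, 1.035168e-06,
            4.367115e-07, 1.293960e-07, 2.794954e-08, 1.204233e-08,
            6.823618e-09, 3.493692e-09, 3.272894e-09, 1.788770e-09,
            1.035168e-09, 4.367115e-10, 1.949277e-10, 1.293960e-10,
        ]),
        'compton': np.array([
            2.033981e-04, 1.873795e-04, 1.784913e-04, 1.606899e-04,
            1.472427e-04, 1.280325e-04, 1.047465e-04, 9.278330e-05,
            8.511092e-05, 7.650714e-05, 7.569419e-05, 6.839722e-05,
            6.215115e-05, 5.301652e-05, 4.530069e-05, 4.169021e-05,
        ]),
        'pair': np.array([
            0.000000e+00, 0.000000e+00, 0.000000e+00, 0.000000e+00,
            0.000000e+00, 0.000000e+00, 0.000000e+00, 0.000000e+00,
            0.000000e+00, 0.000000e+00, 0.000000e+00, 9.537463e-09,
            7.153097e-08, 4.685279e-07, 9.597072e-07, 1.353128e-06,
        ]),
    },
}

# positron CSDA range: kinetic energy (MeV) -> mass range (g/cm^2).
# The bone table differs from water by the Z/A stopping-power ratio;
# other tissues share the water mass-range curve (density-scaled).
CSDA_KE_MEV = np.array(
    [0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1, 1.25, 1.5, 1.75, 2])

CSDA_WATER_GCM2 = np.array(
    [0, 0.000252, 0.000857, 0.00432, 0.01431, 0.04479, 0.084, 0.1285, 0.1766, 0.226, 0.3283, 0.4367, 0.574, 0.708, 0.841, 0.979])

CSDA_BONE_GCM2 = np.array(
    [0, 0.000271729, 0.000924095, 0.00465821, 0.0154303, 0.0482966, 0.0905764, 0.13856, 0.190426, 0.243694, 0.354003, 0.470889, 0.618938, 0.763429, 0.906842, 1.05565])

# radiation length per material, g/cm^2 (PDG element formula, mixed by
# mass fraction); sets the Highland multiple-scattering angle
X0_G_CM2 = {
    'water': 36.3280,
    'adipose': 41.5291,
    'lung': 36.7831,
    'brain': 37.0792,
    'bone': 27.3078,
    'air': 36.8545,
}

# Pb-212 decay-chain gamma lines: (energy MeV, intensity per Pb-212
# decay, emitting nuclide).  The 2.617 MeV Tl-208 line (~99% per Tl-208
# decay x 36% alpha branch of Bi-212) is the imaging line.
PB212_CHAIN_LINES = [
    (0.2386, 0.436, 'Pb-212'),
    (0.3001, 0.033, 'Pb-212'),
    (0.2774, 0.024, 'Tl-208'),
    (0.5107, 0.081, 'Tl-208'),
    (0.5832, 0.306, 'Tl-208'),
    (0.7273, 0.067, 'Bi-212'),
    (0.8606, 0.045, 'Tl-208'),
    (1.6205, 0.015, 'Bi-212'),
    (2.617, 0.36, 'Tl-208'),
]
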