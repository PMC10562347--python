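"""Canonical echocardiographic variable panel.

The default feature panel is the 68-variable set used for the remodelling
model: age and body mass index plus 66 echocardiography measurements
(2D dimensions and volumes, Doppler velocities, tissue Doppler, timing
intervals, and left ventricular / left atrial speckle-tracking strain).
Names are snake_case identifiers; units are noted inline.
"""

from __future__ import annotations

#: The 68 model variables, in conventional reporting order.
ECHO_VARIABLES: list[str] = [
    "age",                              # years
    "body_mass_index",                  # kg/m^2
    "heart_rate",                       # bpm
    "ivs_thickness",                    # interventricular septum, cm
    "lv_internal_diastolic_dimension",  # cm
    "lv_posterior_wall_thickness",      # cm
    "lv_internal_systolic_dimension",   # cm
    "lv_ef_teichholz",                  # %
    "lvot_diameter",                    # cm
    "lv_relative_wall_thickness",
    "lv_mass",                          # g
    "lv_mass_index",                    # g/m^2
    "lv_4ch_edv",                       # ml
    "lv_4ch_esv",                       # ml
    "lv_4ch_ef",                        # %
    "lv_4ch_sv",                        # ml
    "lv_2ch_edv",                       # ml
    "lv_2ch_esv",                       # ml
    "lv_2ch_ef",                        # %
    "lv_2ch_sv",                        # ml
    "lv_biplane_edv",                   # ml
    "lv_biplane_esv",                   # ml
    "lv_biplane_ef",                    # %
    "lv_biplane_sv",                    # ml
    "lv_biplane_cardiac_output",        # ml/min
    "la_4ch_volume",                    # ml
    "la_2ch_volume",                    # ml
    "la_biplane_volume",                # ml
    "mv_e_velocity",                    # cm/s
    "mv_a_velocity",                    # cm/s
    "e_a_ratio",
    "mv_deceleration_time",             # s
    "lateral_s_prime_velocity",         # cm/s
    "lateral_e_prime_velocity",         # cm/s
    "lateral_a_prime_velocity",         # cm/s
    "septal_s_prime_velocity",          # cm/s
    "septal_e_prime_velocity",          # cm/s
    "septal_a_prime_velocity",          # cm/s
    "e_prime_average",                  # cm/s
    "e_over_e_prime_lateral",
    "e_over_e_prime_septal",
    "e_over_e_prime_average",
    "av_max_velocity",                  # cm/s
    "lvot_vti",                         # cm
    "pv_max_velocity",                  # cm/s
    "pa_acceleration_time",             # s
    "rv_basal_dimension",               # cm
    "rv_mid_dimension",                 # cm
    "rv_length",                        # cm
    "ra_volume",                        # ml
    "tr_max_velocity",                  # cm/s
    "tapse",                            # cm
    "rv_s_prime_velocity",              # cm/s
    "rv_e_prime_velocity",              # cm/s
    "rv_a_prime_velocity",              # cm/s
    "ivct",                             # isovolumetric contraction time, s
    "ivrt",                             # isovolumetric relaxation time, s
    "ejection_time",                    # s
    "lv_gls",                           # global longitudinal strain, %
    "la_reservoir_strain_4ch",          # %
    "la_booster_strain_4ch",            # %
    "la_conduit_4ch",                   # %
    "la_reservoir_strain_2ch",          # %
    "la_booster_strain_2ch",            # %
    "la_conduit_2ch",                   # %
    "la_reservoir_strain_biplane",      # %
    "la_booster_strain_biplane",        # %
    "la_conduit_biplane",               # %
]

#: The nine left-atrial strain indices whose exclusion defines the
#: reduced comparison model.
LA_STRAIN_VARIABLES: list[str] = ECHO_VARIABLES[59:68]

# Cohort-level mean and SD used to put simulated variables on realistic
# clinical scales. Variables without a published summary stay unit scale.
CALIBRATED_MOMENTS: dict[str, tuple[float, float]] = {
    "age": (28.9, 5.7),
    "body_mass_index": (26.3, 5.01),
    "heart_rate": (64.61, 11.53),
    "lv_internal_diastolic_dimension": (4.71, 0.48),
    "lv_internal_systolic_dimension": (3.10, 0.44),
    "ivs_thickness": (0.89, 0.20),
    "lv_posterior_wall_thickness": (0.93, 0.18),
    "lv_relative_wall_thickness": (0.40, 0.09),
    "lv_mass_index": (72.38, 18.17),
    "lv_biplane_edv": (99.48, 25.76),
    "lv_biplane_esv": (37.00, 11.79),
    "lv_biplane_ef": (63.09, 5.57),
    "lv_biplane_sv": (62.44, 16.28),
    "mv_e_velocity": (78.81, 15.82),
    "mv_a_velocity": (53.38, 12.59),
    "e_a_ratio": (1.55, 0.44),
    "mv_deceleration_time": (0.19, 0.04),
    "lateral_e_prime_velocity": (15.43, 3.92),
    "septal_e_prime_velocity": (10.67, 2.41),
    "e_over_e_prime_lateral": (5.41, 1.70),
    "e_over_e_prime_septal": (7.67, 1.99),
    "lv_gls": (-20.34, 2.28),
    "la_biplane_volume": (40.55, 11.99),
    "la_reservoir_strain_biplane": (36.75, 7.67),
    "la_booster_strain_biplane": (9.71, 5.26),
    "la_conduit_biplane": (26.95, 7.63),
    "rv_basal_dimension": (3.54, 0.52),
    "rv_mid_dimension": (2.57, 0.54),
    "rv_length": (7.00, 0.88),
    "tapse": (2.16, 0.34),
    "rv_s_prime_velocity": (12.57, 1.94),
    "ra_volume": (37.20, 12.68),
}

# Hypertensive remodelling in young adults is carried mainly by left atrial
# structure/function, left ventricular volumes, and Doppler/diastolic
# indices. The simulator plants its disease factors on these groups, with
# signs matching the expected direction of change as remodelling advances
# (e.g. LA strain falls, LA volume and E/e' rise).
DISEASE_FACTOR_SUPPORT: list[dict[str, float]] = [
    # factor 1: left atrial structure and function
    {
        "la_4ch_volume": +1.0,
        "la_2ch_volume": +1.0,
        "la_biplane_volume": +1.0,
        "la_reservoir_strain_4ch": -1.0,
        "la_conduit_4ch": -1.0,
        "la_reservoir_strain_2ch": -1.0,
        "la_conduit_2ch": -1.0,
        "la_reservoir_strain_biplane": -1.0,
        "la_conduit_biplane": -1.0,
        "la_booster_strain_biplane": +0.5,
    },
    # factor 2: left ventricular volumes and systolic dimension
    {
        "lv_internal_systolic_dimension": +1.0,
        "lv_4ch_edv": -1.0,
        "lv_4ch_esv": -1.0,
        "lv_2ch_edv": -1.0,
        "lv_2ch_esv": -1.0,
        "lv_biplane_edv": -1.0,
        "lv_biplane_esv": -1.0,
        "lv_biplane_sv": -1.0,
    },
    # factor 3: Doppler velocities / diastolic function
    {
        "mv_e_velocity": +0.5,
        "e_a_ratio": -0.7,
        "lateral_e_prime_velocity": -1.0,
        "septal_e_prime_velocity": -1.0,
        "e_prime_average": -1.0,
        "e_over_e_prime_lateral": +1.0,
        "e_over_e_prime_septal": +1.0,
        "e_over_e_prime_average": +1.0,
    },
]
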