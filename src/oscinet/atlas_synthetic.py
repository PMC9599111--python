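"""Synthetic 130-region cortical parcellation table.

This is a *synthetic* stand-in atlas: 65 plausible cortical region names,
mirrored over the two hemispheres (130 parcels), each assigned to one of
8 functional systems (frontoparietal, attention, motor/somatosensory,
cinguloopercular, visual, medial default mode, ventral temporal
association, auditory).  The region names follow common gyral/sulcal
nomenclature, but the table is constructed for simulation and testing —
it is not a redistribution of any published atlas's label file.
"""

from __future__ import annotations

# (base region name, functional system); each appears once per hemisphere.
SYNTHETIC_REGION_TABLE: tuple[tuple[str, str], ...] = (
    # frontoparietal (10)
    ("pars_triangularis", "frontoparietal"),
    ("pars_opercularis", "frontoparietal"),
    ("pars_orbitalis", "frontoparietal"),
    ("middle_frontal_gyrus", "frontoparietal"),
    ("superior_frontal_gyrus", "frontoparietal"),
    ("superior_parietal_gyrus", "frontoparietal"),
    ("angular_gyrus", "frontoparietal"),
    ("intraparietal_sulcus", "frontoparietal"),
    ("inferior_frontal_sulcus", "frontoparietal"),
    ("frontal_pole", "frontoparietal"),
    # attention (7)
    ("supramarginal_gyrus", "attention"),
    ("transverse_frontal_gyrus", "attention"),
    ("frontal_eye_field", "attention"),
    ("temporoparietal_junction", "attention"),
    ("middle_frontal_sulcus", "attention"),
    ("precentral_sulcus", "attention"),
    ("superior_frontal_sulcus", "attention"),
    # motor and somatosensory (8)
    ("precentral_gyrus", "motor_somatosensory"),
    ("postcentral_gyrus", "motor_somatosensory"),
    ("paracentral_lobule", "motor_somatosensory"),
    ("central_sulcus", "motor_somatosensory"),
    ("postcentral_sulcus", "motor_somatosensory"),
    ("supplementary_motor_area", "motor_somatosensory"),
    ("ventral_premotor_cortex", "motor_somatosensory"),
    ("dorsal_premotor_cortex", "motor_somatosensory"),
    # cinguloopercular (8)
    ("insula", "cinguloopercular"),
    ("anterior_cingulate_gyrus", "cinguloopercular"),
    ("middle_cingulate_gyrus", "cinguloopercular"),
    ("posterior_cingulate_gyrus", "cinguloopercular"),
    ("frontal_operculum", "cinguloopercular"),
    ("parietal_operculum", "cinguloopercular"),
    ("subcallosal_gyrus", "cinguloopercular"),
    ("gyrus_rectus", "cinguloopercular"),
    # visual (12)
    ("superior_occipital_gyrus", "visual"),
    ("middle_occipital_gyrus", "visual"),
    ("inferior_occipital_gyrus", "visual"),
    ("cuneus", "visual"),
    ("lingual_gyrus", "visual"),
    ("occipital_pole", "visual"),
    ("calcarine_cortex", "visual"),
    ("pericalcarine_cortex", "visual"),
    ("lateral_occipital_gyrus", "visual"),
    ("transverse_occipital_sulcus", "visual"),
    ("parieto_occipital_sulcus", "visual"),
    ("superior_occipital_sulcus", "visual"),
    # medial default mode (6)
    ("precuneus", "medial_default_mode"),
    ("orbito_frontal_gyrus", "medial_default_mode"),
    ("medial_prefrontal_cortex", "medial_default_mode"),
    ("parahippocampal_gyrus", "medial_default_mode"),
    ("retrosplenial_cortex", "medial_default_mode"),
    ("medial_superior_frontal_gyrus", "medial_default_mode"),
    # ventral temporal association (9)
    ("fusiform_gyrus", "ventral_temporal_association"),
    ("inferior_temporal_gyrus", "ventral_temporal_association"),
    ("middle_temporal_gyrus", "ventral_temporal_association"),
    ("temporal_pole", "ventral_temporal_association"),
    ("entorhinal_cortex", "ventral_temporal_association"),
    ("occipitotemporal_sulcus", "ventral_temporal_association"),
    ("collateral_sulcus", "ventral_temporal_association"),
    ("inferior_temporal_sulcus", "ventral_temporal_association"),
    ("middle_temporal_sulcus", "ventral_temporal_association"),
    # auditory (5)
    ("superior_temporal_gyrus", "auditory"),
    ("transverse_temporal_gyrus", "auditory"),
    ("planum_temporale", "auditory"),
    ("planum_polare", "auditory"),
    ("superior_temporal_sulcus", "auditory"),
)

assert len(SYNTHETIC_REGION_TABLE) == 65
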