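[
 "length",
 "molecular_weight",
 "aromaticity",
 "instability_index",
 "gravy",
 "isoelectric_point",
 "charge_at_pH7",
 "ss_helix_fraction",
 "ss_turn_fraction",
 "ss_sheet_fraction",
 "extinction_coeff_reduced",
 "extinction_coeff_oxidized",
 "flexibility_profile_mean",
 "flexibility_profile_sd",
 "flexibility_profile_min",
 "flexibility_profile_max",
 "hydropathy_kd_mean",
 "hydropathy_kd_sd",
 "hydropathy_kd_min",
 "hydropathy_kd_max",
 "hydropathy_kd_range",
 "hydropathy_kd_q25",
 "hydropathy_kd_median",
 "hydropathy_kd_q75",
 "hydropathy_kd_mean_first_half",
 "hydropathy_kd_mean_second_half",
 "hydrophilicity_hw_mean",
 "hydrophilicity_hw_sd",
 "hydrophilicity_hw_min",
 "hydrophilicity_hw_max",
 "hydrophilicity_hw_range",
 "hydrophilicity_hw_q25",
 "hydrophilicity_hw_median",
 "hydrophilicity_hw_q75",
 "hydrophilicity_hw_mean_first_half",
 "hydrophilicity_hw_mean_second_half",
 "surface_accessibility_em_mean",
 "surface_accessibility_em_sd",
 "surface_accessibility_em_min",
 "surface_accessibility_em_max",
 "surface_accessibility_em_range",
 "surface_accessibility_em_q25",
 "surface_accessibility_em_median",
 "surface_accessibility_em_q75",
 "surface_accessibility_em_mean_first_half",
 "surface_accessibility_em_mean_second_half",
 "buried_fraction_ja_mean",
 "buried_fraction_ja_sd",
 "buried_fraction_ja_min",
 "buried_fraction_ja_max",
 "buried_fraction_ja_range",
 "buried_fraction_ja_q25",
 "buried_fraction_ja_median",
 "buried_fraction_ja_q75",
 "buried_fraction_ja_mean_first_half",
 "buried_fraction_ja_mean_second_half",
 "flexibility_vihinen_mean",
 "flexibility_vihinen_sd",
 "flexibility_vihinen_min",
 "flexibility_vihinen_max",
 "flexibility_vihinen_range",
 "flexibility_vihinen_q25",
 "flexibility_vihinen_median",
 "flexibility_vihinen_q75",
 "flexibility_vihinen_mean_first_half",
 "flexibility_vihinen_mean_second_half",
 "residue_mass_mean",
 "residue_mass_sd",
 "residue_mass_min",
 "residue_mass_max",
 "residue_mass_range",
 "residue_mass_q25",
 "residue_mass_median",
 "residue_mass_q75",
 "residue_mass_mean_first_half",
 "residue_mass_mean_second_half",
 "polarity_grantham_mean",
 "polarity_grantham_sd",
 "polarity_grantham_min",
 "polarity_grantham_max",
 "polarity_grantham_range",
 "polarity_grantham_q25",
 "polarity_grantham_median",
 "polarity_grantham_q75",
 "polarity_grantham_mean_first_half",
 "polarity_grantham_mean_second_half",
 "volume_zamyatnin_mean",
 "volume_zamyatnin_sd",
 "volume_zamyatnin_min",
 "volume_zamyatnin_max",
 "volume_zamyatnin_range",
 "volume_zamyatnin_q25",
 "volume_zamyatnin_median",
 "volume_zamyatnin_q75",
 "volume_zamyatnin_mean_first_half",
 "volume_zamyatnin_mean_second_half",
 "polarizability_charton_mean",
 "polarizability_charton_sd",
 "polarizability_charton_min",
 "polarizability_charton_max",
 "polarizability_charton_range",
 "polarizability_charton_q25",
 "polarizability_charton_median",
 "polarizability_charton_q75",
 "polarizability_charton_mean_first_half",
 "polarizability_charton_mean_second_half",
 "free_energy_charton_mean",
 "free_energy_charton_sd",
 "free_energy_charton_min",
 "free_energy_charton_max",
 "free_energy_charton_range",
 "free_energy_charton_q25",
 "free_energy_charton_median",
 "free_energy_charton_q75",
 "free_energy_charton_mean_first_half",
 "free_energy_charton_mean_second_half",
 "steric_charton_mean",
 "steric_charton_sd",
 "steric_charton_min",
 "steric_charton_max",
 "steric_charton_range",
 "steric_charton_q25",
 "steric_charton_median",
 "steric_charton_q75",
 "steric_charton_mean_first_half",
 "steric_charton_mean_second_half",
 "bulkiness_zimmerman_mean",
 "bulkiness_zimmerman_sd",
 "bulkiness_zimmerman_min",
 "bulkiness_zimmerman_max",
 "bulkiness_zimmerman_range",
 "bulkiness_zimmerman_q25",
 "bulkiness_zimmerman_median",
 "bulkiness_zimmerman_q75",
 "bulkiness_zimmerman_mean_first_half",
 "bulkiness_zimmerman_mean_second_half",
 "vdw_volume_norm_mean",
 "vdw_volume_norm_sd",
 "vdw_volume_norm_min",
 "vdw_volume_norm_max",
 "vdw_volume_norm_range",
 "vdw_volume_norm_q25",
 "vdw_volume_norm_median",
 "vdw_volume_norm_q75",
 "vdw_volume_norm_mean_first_half",
 "vdw_volume_norm_mean_second_half",
 "pI_residue_mean",
 "pI_residue_sd",
 "pI_residue_min",
 "pI_residue_max",
 "pI_residue_range",
 "pI_residue_q25",
 "pI_residue_median",
 "pI_residue_q75",
 "pI_residue_mean_first_half",
 "pI_residue_mean_second_half"
]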