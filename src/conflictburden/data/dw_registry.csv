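code,description,variant,mean,ui_lower,ui_upper
st_minor,"Minor short-term injury (superficial wound, contusion)",single,0.006,0.002,0.012
st_moderate,"Moderate short-term injury (limb fracture, penetrating wound)",single,0.051,0.032,0.074
st_severe,"Severe short-term injury (multiple trauma, internal injury)",single,0.133,0.089,0.186
lt_musculoskeletal,"Long-term musculoskeletal impairment of a limb",treated,0.116,0.077,0.164
lt_musculoskeletal,"Long-term musculoskeletal impairment of a limb",untreated,0.233,0.157,0.327
lt_amputation,"Traumatic amputation of a limb",treated,0.039,0.024,0.059
lt_amputation,"Traumatic amputation of a limb",untreated,0.164,0.110,0.229
lt_spinal_cord,"Spinal cord lesion",treated,0.296,0.198,0.414
lt_spinal_cord,"Spinal cord lesion",untreated,0.589,0.404,0.762
lt_severe_tbi,"Severe traumatic brain injury with lasting impairment",treated,0.203,0.134,0.288
lt_severe_tbi,"Severe traumatic brain injury with lasting impairment",untreated,0.442,0.299,0.600
lt_burn_disfigurement,"Extensive burn with disfigurement",treated,0.188,0.124,0.267
lt_burn_disfigurement,"Extensive burn with disfigurement",untreated,0.405,0.272,0.552
lt_vision_loss,"Traumatic loss of vision",treated,0.184,0.121,0.262
lt_vision_loss,"Traumatic loss of vision",untreated,0.338,0.226,0.466
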