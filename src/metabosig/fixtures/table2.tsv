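metabolite	all	age_gt_50	males	males_age_gt_50	females	females_age_gt_50	bmi_ge_30	age_gt_50_bmi_ge_30	bmi_lt_30	age_gt_50_bmi_lt_30
lysoPCaC16:0								0.66		
lysoPCaC28:1	0.6	0.64	0.64	0.67						0.66
PCaaC28:1			0.62	0.65						
PCaaC32:3	0.61	0.67	0.69	0.70		0.66	0.62	0.69		0.64
PCaaC34:3		0.62	0.65	0.68						
PCaaC36:0	0.6	0.62	0.63	0.66						
PCaaC36:2				0.65						
PCaaC36:5		0.61		0.69						
PCaaC36:6	0.59	0.64	0.64	0.70						
PCaaC38:0	0.59	0.64	0.67	0.72						
PCaaC38:5		0.61	0.64	0.68						
PCaaC38:6		0.61		0.65						
PCaaC40:1		0.61	0.63	0.67						
PCaaC40:2				0.65						
PCaaC40:6				0.65						
PCaaC42:0			0.62							
PCaaC42:2	0.59	0.63		0.66						0.65
PCaaC42:5				0.66						
PCaeC30:1			0.64	0.68						
PCaeC30:2	0.59	0.63	0.65	0.68						
PCaeC32:2	0.6	0.65	0.65	0.69				0.68		
PCaeC34:0		0.6								
PCaeC34:1		0.61								
PCaeC34:2		0.62		0.65						
PCaeC34:3		0.62		0.64						
PCaeC36:2	0.59	0.64	0.62	0.67				0.66		
PCaeC36:3	0.59	0.64	0.63	0.66				0.67		
PCaeC38:0	0.61	0.66	0.68	0.74						0.67
PCaeC38:1		0.61		0.64						
PCaeC38:2	0.6	0.66	0.65	0.69						0.67
PCaeC38:3		0.61						0.65		
PCaeC38:5		0.6								
PCaeC38:6	0.6	0.65	0.66	0.72				0.64		
PCaeC40:1		0.63		0.65						0.67
PCaeC40:2		0.61		0.67						
PCaeC40:5	0.61	0.63	0.63	0.67				0.67		
PCaeC40:6	0.62	0.67	0.64	0.7				0.67		0.63
PCaeC42:2		0.61								
PCaeC42:3		0.61		0.64						
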