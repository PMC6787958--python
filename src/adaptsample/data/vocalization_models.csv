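species_code,covariate,transform,period,coefficient
BTGN,,intercept,,-0.3
BTGN,day_of_year,identity,,-0.002
BTGN,day_of_year,sin_period,366,1
BTGN,hour_of_day,cos_period,12,-0.5
BTGN,time_to_sunrise,square,,-0.000007
BTGN,temperature,identity,,0.009
BTGN,temperature,cube,,-0.000001
BTGN,wind_speed,identity,,-0.35
COPO,,intercept,,-1.5
COPO,day_of_year,identity,,-0.003
COPO,day_of_year,cos_period,366,-0.5
COPO,day_of_year,sin_period,366,0.6
COPO,hour_of_day,cos_period,24,1
COPO,hour_of_day,cos_period,12,-0.5
COPO,time_to_sunrise,identity,,-0.0005
COPO,time_to_sunset,identity,,-0.0005
COPO,wind_speed,identity,,-0.1
COPO,lunar_phase,cos_lunar,,-0.2
TOAD,,intercept,,-8
TOAD,day_of_year,cos_period,366,-1
TOAD,day_of_year,sin_period,366,-2
TOAD,hour_of_day,cos_period,24,3
TOAD,rain_accum_24h,identity,,5
COYOTE,,intercept,,-3
COYOTE,day_of_year_equinox,cos_period,183,-0.5
COYOTE,day_of_year_equinox,sin_period,183,0.2
COYOTE,hour_of_day,cos_period,24,1
COYOTE,hour_of_day,cos_period,12,-0.5
COYOTE,time_to_sunrise,identity,,-0.001
COYOTE,time_to_sunset,identity,,-0.001
COYOTE,lunar_phase,cos_lunar,,0.2
ECDO,,intercept,,-1.4
ECDO,day_of_year,sin_period,366,1
ECDO,hour_of_day,cos_period,12,-2
ECDO,time_to_sunrise,square,,-0.000005
ECDO,temperature,identity,,0.009
ECDO,temperature,cube,,-0.000001
ECDO,wind_speed,identity,,-0.25
GAQU,,intercept,,-1.2
GAQU,day_of_year,identity,,-0.002
GAQU,day_of_year,sin_period,366,1.3
GAQU,hour_of_day,cos_period,12,-2
GAQU,time_to_sunrise,square,,-0.000005
GAQU,temperature,identity,,0.009
GAQU,temperature,cube,,-0.000001
GAQU,wind_speed,identity,,-0.25
LENI,,intercept,,-2
LENI,day_of_year,identity,,-0.006
LENI,day_of_year,cos_period,366,0.4
LENI,day_of_year,sin_period,366,0.7
LENI,hour_of_day,cos_period,24,1
LENI,hour_of_day,cos_period,12,-0.5
LENI,time_to_sunrise,identity,,-0.0005
LENI,time_to_sunset,identity,,-0.0005
LENI,wind_speed,identity,,-0.25
LENI,lunar_phase,cos_lunar,,-0.3
PHAI,,intercept,,-2.2
PHAI,day_of_year,square,,-0.00001
PHAI,day_of_year,cos_period,366,0.7
PHAI,day_of_year,sin_period,366,2.2
PHAI,hour_of_day,cos_period,12,-2.5
PHAI,time_to_sunrise,square,,-0.000004
PHAI,temperature,identity,,0.009
PHAI,temperature,cube,,-0.000001
PHAI,wind_speed,identity,,-0.25
VERD,,intercept,,-0.5
VERD,day_of_year,identity,,-0.004
VERD,day_of_year,sin_period,366,1
VERD,hour_of_day,cos_period,12,-1.5
VERD,time_to_sunrise,square,,-0.000007
VERD,temperature,identity,,0.009
VERD,temperature,cube,,-0.000001
VERD,wind_speed,identity,,-0.25
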