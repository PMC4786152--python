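name,specification,details
countrytable,basic_cd4_country,Table with one row per country and time point
var,proportion,Proportion (0-1) or percentage (0-100) column
country,iso3,ISO-3 country code column
year,year,Time point column
varlabel,Proportion CD4<200 at HIV diagnosis,
varscale,proportion,
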