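soil_id,property,value,unit
N,pH,7.39,pH
A,pH,8.29,pH
N,total_water_soluble_salts,0.04,g/kg
A,total_water_soluble_salts,1.10,g/kg
N,electrical_conductivity,482.3,uS/cm
A,electrical_conductivity,1217.7,uS/cm
N,organic_matter,30.5,g/kg
A,organic_matter,24.78,g/kg
N,available_potassium,96,mg/kg
A,available_potassium,144.39,mg/kg
N,available_nitrogen,129.76,mg/kg
A,available_nitrogen,145.18,mg/kg
N,available_phosphorus,55.74,mg/kg
A,available_phosphorus,13.04,mg/kg
N,sodium_ion,22.32,mg/kg
A,sodium_ion,109.45,mg/kg
N,potassium_ion,4.21,mg/kg
A,potassium_ion,12.28,mg/kg
N,calcium_ion,49,mg/kg
A,calcium_ion,129.53,mg/kg
N,magnesium_ion,14,mg/kg
A,magnesium_ion,17.97,mg/kg
N,sulfate,<0.02,g/kg
A,sulfate,0.02,g/kg
N,carbonate,<0.01,g/kg
A,carbonate,0.01,g/kg
N,bicarbonate,0.19,g/kg
A,bicarbonate,0.51,g/kg
N,chloride_ion,0.02,g/kg
A,chloride_ion,0.03,g/kg
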