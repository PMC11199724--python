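Argentina
Australia
Austria
Belgium
Bolivia
Brazil
Canada
Chile
China
Colombia
Cuba
Czech Republic
Denmark
Ecuador
Egypt
Finland
France
French Guiana
Germany
Greece
Guyana
Hungary
India
Indonesia
Iran
Ireland
Israel
Italy
Japan
Malaysia
Mexico
Netherlands
New Zealand
Nigeria
Norway
Pakistan
Panama
Paraguay
Peru
Poland
Portugal
Romania
Russian Federation
Saudi Arabia
Singapore
South Africa
South Korea
Spain
Suriname
Sweden
Switzerland
Taiwan
Thailand
Turkey
Ukraine
United Kingdom
United States
Uruguay
Venezuela
Vietnam
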