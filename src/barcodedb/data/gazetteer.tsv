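country	continent	realm
Germany	Europe	Palearctic
Austria	Europe	Palearctic
France	Europe	Palearctic
Spain	Europe	Palearctic
Portugal	Europe	Palearctic
Italy	Europe	Palearctic
Netherlands	Europe	Palearctic
Belgium	Europe	Palearctic
Switzerland	Europe	Palearctic
Poland	Europe	Palearctic
Czech Republic	Europe	Palearctic
Denmark	Europe	Palearctic
Sweden	Europe	Palearctic
Norway	Europe	Palearctic
Finland	Europe	Palearctic
United Kingdom	Europe	Palearctic
Ireland	Europe	Palearctic
Greece	Europe	Palearctic
Russia	Europe	Palearctic
Canada	North America	Nearctic
United States	North America	Nearctic
Mexico	North America	Neotropic
Costa Rica	North America	Neotropic
Honduras	North America	Neotropic
Panama	North America	Neotropic
Brazil	South America	Neotropic
Argentina	South America	Neotropic
Chile	South America	Neotropic
Peru	South America	Neotropic
Colombia	South America	Neotropic
Ecuador	South America	Neotropic
China	Asia	Palearctic
Japan	Asia	Palearctic
Mongolia	Asia	Palearctic
India	Asia	Indomalayan
Thailand	Asia	Indomalayan
Vietnam	Asia	Indomalayan
Malaysia	Asia	Indomalayan
Indonesia	Asia	Indomalayan
Philippines	Asia	Indomalayan
South Africa	Africa	Afrotropic
Kenya	Africa	Afrotropic
Tanzania	Africa	Afrotropic
Madagascar	Africa	Afrotropic
Nigeria	Africa	Afrotropic
Morocco	Africa	Palearctic
Egypt	Africa	Palearctic
Australia	Oceania	Australasian
New Zealand	Oceania	Australasian
Papua New Guinea	Oceania	Australasian
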