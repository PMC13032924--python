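species,group,song_peak_freq_khz,song_source_level_db,flight_speed_m_s,fend_lo_khz,fend_hi_khz,provenance
Nyctalus noctula,Nyctaloid,15.0,84.0,6.0,8.0,22.0,"freq/SL plausible within published range; flight speed published"
Nyctalus leisleri,Nyctaloid,16.0,82.0,5.5,22.0,29.0,"freq/SL plausible within published range; flight speed placeholder"
Vespertilio murinus,Nyctaloid,14.0,108.0,5.0,22.0,29.0,"freq/SL published range endpoints; flight speed placeholder"
Plecotus spp.,Nyctaloid,26.4,83.45,2.5,22.0,29.0,"freq published range endpoint; SL calibrated to published 25.1 m detection range; flight speed published"
Pipistrellus nathusii,Pipistrelloid,19.0,102.93,4.5,30.0,42.0,"freq plausible; SL calibrated to published 100 m active space; flight speed placeholder"
Pipistrellus pipistrellus,Pipistrelloid,21.0,87.0,4.0,42.0,51.0,"freq/SL plausible within published range; flight speed placeholder"
Pipistrellus pygmaeus,Pipistrelloid,23.0,72.0,3.5,51.0,65.0,"freq plausible; SL published range endpoint; flight speed placeholder"
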