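import numpy as np
import pytest

from pbs_lfqa import (
    AmbientConditions,
    MachineGeometry,
    charge_to_mu,
    fit_strip_centroid,
    project_to_isocenter,
    read_fraction,
    simulate_fraction,
    synthesize_strip_profile,
    write_fraction_logs,
)
from pbs_lfqa.errors import (
    CoverageError,
    FormatError,
    GeometryError,
    IntegrityError,
    InvalidDataError,
)
from pbs_lfqa.logfile_io import (
    events_filename,
    record_filename,
    strip_positions,
)


# ---------------------------------------------------------------- centroid


def test_centroid_of_symmetric_profile_is_grid_center(geometry):
    x = strip_positions(geometry)
    q = np.exp(-0.5 * (x / 5.0) ** 2)
    assert fit_strip_centroid(q, x) == pytest.approx(0.0, abs=1e-9)


def test_centroid_translation_equivariance(geometry):
    x = strip_positions(geometry)
    q = synthesize_strip_profile(1.7, 4.0, 1.0, geometry)
    shifted = np.roll(q, 1)  # profile moved one strip towards +x
    c0 = fit_strip_centroid(q, x)
    c1 = fit_strip_centroid(shifted, x)
    assert c1 - c0 == pytest.approx(geometry.strip_pitch, abs=1e-6)


def test_centroid_peak_on_boundary_is_coverage_error(geometry):
    x = strip_positions(geometry)
    q = np.exp(-0.5 * ((x - x[-1]) / 4.0) ** 2)
    with pytest.raises(CoverageError):
        fit_strip_centroid(q, x)


def test_centroid_requires_positive_charge(geometry):
    x = strip_positions(geometry)[:7]
    with pytest.raises(InvalidDataError):
        fit_strip_centroid(np.zeros(7), x)


# ---------------------------------------------------------------- projection


def test_projection_similar_triangles():
    g = MachineGeometry(sad_x=2000.0, sad_y=2000.0, z_ic=500.0)
    assert project_to_isocenter(10.0, "x", g) == pytest.approx(40.0 / 3.0)
    assert project_to_isocenter(0.0, "y", g) == 0.0


def test_projection_parallel_beam_limit():
    g = MachineGeometry(sad_x=1e12, sad_y=1e12, z_ic=500.0)
    assert project_to_isocenter(7.3, "x", g) == pytest.approx(7.3, rel=1e-6)


def test_projection_is_linear(geometry):
    a = project_to_isocenter(3.0, "x", geometry)
    b = project_to_isocenter(5.0, "x", geometry)
    assert project_to_isocenter(8.0, "x", geometry) == pytest.approx(a + b)


def test_projection_invalid_geometry_rejected():
    with pytest.raises(GeometryError):
        MachineGeometry(sad_x=400.0, sad_y=2000.0, z_ic=450.0)


# ---------------------------------------------------------------- MU


def test_charge_to_mu_reference_conditions(geometry):
    mu = charge_to_mu(2.0, 0.5, AmbientConditions(), geometry)
    assert mu == pytest.approx(1.0)


def test_charge_to_mu_pressure_halved_doubles_mu(geometry):
    ref = AmbientConditions()
    half = AmbientConditions(pressure=ref.pressure / 2.0)
    assert charge_to_mu(1.0, 1.0, half, geometry) == pytest.approx(
        2.0 * charge_to_mu(1.0, 1.0, ref, geometry)
    )


def test_charge_to_mu_linear_in_charge(geometry):
    cond = AmbientConditions(pressure=990.0, temperature=296.0)
    one = charge_to_mu(1.0, 3.0, cond, geometry)
    assert charge_to_mu(4.5, 3.0, cond, geometry) == pytest.approx(4.5 * one)


# ---------------------------------------------------------------- round trip


def _write_and_read(fx, plan, geometry, tmp_path):
    write_fraction_logs(fx, plan, geometry, tmp_path)
    recs = [tmp_path / record_filename(fx.fraction_index, fid)
            for fid in fx.field_ids]
    evs = [tmp_path / events_filename(fx.fraction_index, fid)
           for fid in fx.field_ids]
    return read_fraction(recs, evs, plan, geometry,
                         fraction_index=fx.fraction_index)


def test_writer_reader_roundtrip(small_plan, geometry, default_errors,
                                 tmp_path):
    fx = simulate_fraction(small_plan, geometry, default_errors, 2)
    back = _write_and_read(fx, small_plan, geometry, tmp_path)
    assert not back.aborted
    m1, m2 = fx.spot_map(), back.spot_map()
    assert set(m1) == set(m2)
    for k in m1:
        assert m2[k].x_log == pytest.approx(m1[k].x_log, abs=1e-9)
        assert m2[k].y_log == pytest.approx(m1[k].y_log, abs=1e-9)
        assert m2[k].mu_log == pytest.approx(m1[k].mu_log, abs=1e-9)
        assert m2[k].t_start == m1[k].t_start
        assert m2[k].t_end == m1[k].t_end
    assert [e.kind for e in back.events] == [e.kind for e in fx.events]


def test_truncated_record_flags_aborted(small_plan, geometry, zero_errors,
                                        tmp_path):
    fx = simulate_fraction(small_plan, geometry, zero_errors, 1)
    write_fraction_logs(fx, small_plan, geometry, tmp_path)
    rec = tmp_path / record_filename(1, "F0")
    lines = rec.read_text().splitlines()
    # keep header + first layer only (layer_index column == "0")
    kept = [ln for ln in lines
            if ln.startswith("#") or not ln[0].isdigit() or
            ln.split(",")[0] == "0"]
    rec.write_text("\n".join(kept) + "\n")
    back = read_fraction(
        [rec, tmp_path / record_filename(1, "F1")],
        [tmp_path / events_filename(1, "F0"),
         tmp_path / events_filename(1, "F1")],
        small_plan, geometry,
    )
    assert back.aborted


def test_duplicate_spot_key_is_integrity_error(small_plan, geometry,
                                               zero_errors, tmp_path):
    fx = simulate_fraction(small_plan, geometry, zero_errors, 1)
    write_fraction_logs(fx, small_plan, geometry, tmp_path)
    rec = tmp_path / record_filename(1, "F0")
    lines = rec.read_text().splitlines()
    lines.append(lines[-1])  # duplicate last spot row
    rec.write_text("\n".join(lines) + "\n")
    with pytest.raises(IntegrityError):
        read_fraction(
            [rec, tmp_path / record_filename(1, "F1")],
            [tmp_path / events_filename(1, "F0"),
             tmp_path / events_filename(1, "F1")],
            small_plan, geometry,
        )


def test_unknown_columns_are_format_error_with_line(small_plan, geometry,
                                                    tmp_path):
    bad = tmp_path / "bad.record.csv"
    bad.write_text("# field_id=F0\nfoo,bar\n1,2\n")
    with pytest.raises(FormatError, match="bad.record.csv:2"):
        read_fraction([bad], [], small_plan, geometry)


def test_pre_projected_dialect_accepted(small_plan, geometry, zero_errors,
                                        tmp_path):
    """Records may carry isocenter-plane mm and MU directly."""
    fx = simulate_fraction(small_plan, geometry, zero_errors, 1)
    for fid in fx.field_ids:
        path = tmp_path / record_filename(1, fid)
        with open(path, "w") as fh:
            fh.write(f"# field_id={fid}\n")
            fh.write("layer_index,energy_mev,spot_index,x_iso_mm,y_iso_mm,"
                     "mu,t_start_us,t_end_us\n")
            for s in fx.spots_of_field(fid):
                fh.write(f"{s.layer_index},100.0,{s.spot_index},"
                         f"{s.x_log!r},{s.y_log!r},{s.mu_log!r},"
                         f"{s.t_start},{s.t_end}\n")
        (tmp_path / events_filename(1, fid)).write_text("")
    back = read_fraction(
        [tmp_path / record_filename(1, fid) for fid in fx.field_ids],
        [tmp_path / events_filename(1, fid) for fid in fx.field_ids],
        small_plan, geometry,
    )
    for k, s in fx.spot_map().items():
        b = back.spot_map()[k]
        assert (b.x_log, b.y_log, b.mu_log) == (s.x_log, s.y_log, s.mu_log)


def test_fit_project_recovers_isocenter_ground_truth(geometry):
    """Strip fit + projection recover the true isocenter position < 1 um."""
    x_iso_true = 4.25
    x_ic = x_iso_true / geometry.projection_factor("x")
    q = synthesize_strip_profile(x_ic, 4.0, 1.0, geometry)
    fitted_ic = fit_strip_centroid(q, strip_positions(geometry))
    x_iso = project_to_isocenter(fitted_ic, "x", geometry)
    assert x_iso == pytest.approx(x_iso_true, abs=1e-3)
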